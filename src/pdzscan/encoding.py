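"""Fixed-length numeric feature encodings of domain-peptide pairs.

Three encodings are supported:

``contact_map``
    For each of the map's (domain position, peptide position) pairs the
    residue pair is one-hot encoded in a 400-bit (20 x 20) block; the
    full vector is ``400 * n_pairs`` bits (15,200 for the default
    38-pair map).  A gap at the domain position leaves its block all
    zero.

``binary_sequence``
    Concatenated length-20 one-hot blocks for the 16 binding-site
    columns followed by the 5 peptide residues (420 bits).

``physicochemical``
    The same residue order, each residue replaced by a 5-number
    physicochemical descriptor (105 values), scaled to [0, 1] per
    descriptor dimension over the 20 amino acids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .alphabet import AA_INDEX, GAP, N_AA, check_binding_site, check_peptide
from .data_io import ContactMapDef, Domain, default_contact_map

logger = logging.getLogger(__name__)

ENCODINGS = ("contact_map", "binary_sequence", "physicochemical")

BLOCK = N_AA * N_AA  # one 20x20 residue-pair block
N_RESIDUES = 16 + 5  # binding-site columns + peptide positions


def load_physchem_table() -> dict[str, np.ndarray]:
    """The shipped five-factor amino-acid descriptor table.

    Factor scores of Atchley et al. (2005) — five numbers per residue
    summarizing polarity, secondary-structure propensity, size, codon
    composition and charge — min-max scaled to [0, 1] per factor over
    the 20 amino acids.
    """
    ref = resources.files("pdzscan.data") / "atchley_factors.tsv"
    with resources.as_file(ref) as path:
        frame = pd.read_csv(path, sep="\t", index_col="aa")
    values = frame.to_numpy(dtype=float)
    lo, hi = values.min(axis=0), values.max(axis=0)
    scaled = (values - lo) / (hi - lo)
    return {aa: scaled[i] for i, aa in enumerate(frame.index)}


def vector_length(method: str, cmap: ContactMapDef | None = None) -> int:
    if method == "contact_map":
        cmap = cmap or default_contact_map()
        return BLOCK * len(cmap)
    if method == "binary_sequence":
        return N_AA * N_RESIDUES
    if method == "physicochemical":
        return 5 * N_RESIDUES
    raise ValueError(f"unknown encoding {method!r}")


def contact_map_indices(domain: Domain, peptide: str, cmap: ContactMapDef) -> list[int]:
    """Set-bit indices of the contact-map encoding (one per gap-free pair).

    Pair k with domain residue a and peptide residue b sets bit
    ``k*400 + index(a)*20 + index(b)``; a gapped domain position
    contributes nothing.
    """
    check_binding_site(domain.binding_site)
    check_peptide(peptide)
    indices = []
    for k, (dpos, ppos) in enumerate(cmap.pairs):
        a = domain.binding_site[dpos - 1]
        if a == GAP:
            logger.debug("domain %s: gap at position %d leaves block %d zero",
                         domain.id, dpos, k)
            continue
        b = peptide[ppos + 4]  # p-4..p0 -> string index 0..4
        indices.append(k * BLOCK + AA_INDEX[a] * N_AA + AA_INDEX[b])
    return indices


@dataclass(frozen=True)
class FeatureVector:
    """A fixed-length numeric encoding of one domain-peptide pair."""

    values: np.ndarray
    encoding: str

    def __len__(self) -> int:
        return len(self.values)


def _site_and_peptide(domain: Domain, peptide: str) -> str:
    check_binding_site(domain.binding_site)
    check_peptide(peptide)
    return domain.binding_site + peptide


def encode(
    domain: Domain,
    peptide: str,
    method: str = "contact_map",
    cmap: ContactMapDef | None = None,
    table: dict[str, np.ndarray] | None = None,
) -> FeatureVector:
    """Encode one domain-peptide pair as a dense feature vector."""
    if method == "contact_map":
        cmap = cmap or default_contact_map()
        values = np.zeros(BLOCK * len(cmap))
        values[contact_map_indices(domain, peptide, cmap)] = 1.0
    elif method == "binary_sequence":
        residues = _site_and_peptide(domain, peptide)
        values = np.zeros(N_AA * N_RESIDUES)
        for i, ch in enumerate(residues):
            if ch != GAP:
                values[i * N_AA + AA_INDEX[ch]] = 1.0
    elif method == "physicochemical":
        table = table if table is not None else load_physchem_table()
        residues = _site_and_peptide(domain, peptide)
        values = np.zeros(5 * N_RESIDUES)
        for i, ch in enumerate(residues):
            if ch != GAP:
                values[i * 5 : (i + 1) * 5] = table[ch]
    else:
        raise ValueError(f"unknown encoding {method!r}")
    return FeatureVector(values, method)


def encode_pairs(
    pairs: list[tuple[Domain, str]],
    method: str = "contact_map",
    cmap: ContactMapDef | None = None,
    table: dict[str, np.ndarray] | None = None,
):
    """Encode many pairs at once.

    Returns a CSR sparse matrix for the (very sparse) contact-map
    encoding and a dense ndarray for the other two.
    """
    if method == "contact_map":
        cmap = cmap or default_contact_map()
        width = BLOCK * len(cmap)
        rows, cols = [], []
        for r, (dom, pep) in enumerate(pairs):
            idx = contact_map_indices(dom, pep, cmap)
            rows.extend([r] * len(idx))
            cols.extend(idx)
        data = np.ones(len(rows))
        return sp.csr_matrix((data, (rows, cols)), shape=(len(pairs), width))
    return np.vstack([encode(d, p, method, cmap, table).values for d, p in pairs])


@dataclass
class Scaler:
    """Per-dimension min-max scaler fitted on training vectors.

    Binary encodings pass through unchanged (already in {0, 1}).
    Transformed values are clipped to [0, 1]; constant training
    dimensions map to 0 by convention.
    """

    identity: bool
    lo: np.ndarray | None = None
    span: np.ndarray | None = None


def fit_scaler(training, encoding: str) -> Scaler:
    """Fit the scaler appropriate for the encoding on training data."""
    if encoding in ("contact_map", "binary_sequence"):
        return Scaler(identity=True)
    X = np.asarray(training, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise ValueError("training matrix must be non-empty and 2-D")
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0] = np.inf  # constant dimension -> scales to 0
    return Scaler(identity=False, lo=lo, span=span)


def apply_scaler(scaler: Scaler, X):
    if scaler.identity:
        return X
    X = np.asarray(X, dtype=float)
    return np.clip((X - scaler.lo) / scaler.span, 0.0, 1.0)


def export_sparse(X, y, path: str | Path) -> None:
    """Write labelled vectors in the sparse ``label index:value`` text form
    understood by standard SVM tooling (1-based feature indices)."""
    from sklearn.datasets import dump_svmlight_file

    dump_svmlight_file(X, y, str(path), zero_based=False)
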