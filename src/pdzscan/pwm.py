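"""Position weight matrices over the five C-terminal peptide positions.

A PWM holds, for each ligand position p-4..p0, the probability of
observing each of the 20 amino acids there.  PWMs summarize a domain's
binding specificity, score candidate peptides (sum of per-position log2
probabilities), select artificial negatives, and back the
nearest-neighbour PWM-ensemble baseline predictor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alphabet import AA_INDEX, AMINO_ACIDS, N_AA, PEPTIDE_LENGTH, check_peptide
from .data_io import Domain, InteractionSet
from .similarity import binding_site_similarity

logger = logging.getLogger(__name__)

POSITION_LABELS = ["p-4", "p-3", "p-2", "p-1", "p0"]


@dataclass(frozen=True)
class PWM:
    """A 20 x 5 column-stochastic probability matrix.

    Rows follow the alphabetical amino-acid order of
    :data:`pdzscan.alphabet.AMINO_ACIDS`; columns are ligand positions
    p-4..p0 left to right.
    """

    matrix: np.ndarray
    pseudocount: float = 0.0
    n_sequences: int = 0

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (N_AA, PEPTIDE_LENGTH):
            raise ValueError(f"PWM matrix must be {N_AA}x{PEPTIDE_LENGTH}, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("PWM probabilities must be non-negative")
        if not np.allclose(m.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must each sum to 1")
        object.__setattr__(self, "matrix", m)

    def consensus(self) -> str:
        """Highest-probability residue at each position (ties: alphabetical)."""
        return "".join(AMINO_ACIDS[i] for i in self.matrix.argmax(axis=0))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(AMINO_ACIDS), columns=POSITION_LABELS)


def build_pwm(peptides: list[str], pseudocount: float = 0.01) -> PWM:
    """Estimate a PWM from 5-mer peptides with additive smoothing.

    cell(a, j) = (count(a at j) + pseudocount) / (n + 20 * pseudocount).
    """
    if not peptides:
        raise ValueError("cannot build a PWM from an empty peptide list")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    counts = np.zeros((N_AA, PEPTIDE_LENGTH))
    for pep in peptides:
        check_peptide(pep)
        for j, aa in enumerate(pep):
            counts[AA_INDEX[aa], j] += 1
    n = len(peptides)
    matrix = (counts + pseudocount) / (n + N_AA * pseudocount)
    return PWM(matrix, pseudocount=pseudocount, n_sequences=n)


def score_peptide(pwm: PWM, peptide: str, strict: bool = False) -> float:
    """Sum of log2 cell probabilities for the peptide's residues.

    A zero-probability cell (possible only with pseudocount 0) yields
    ``-inf``, or raises ``ValueError`` when ``strict``.
    """
    check_peptide(peptide)
    total = 0.0
    for j, aa in enumerate(peptide):
        p = pwm.matrix[AA_INDEX[aa], j]
        if p == 0.0:
            if strict:
                raise ValueError(f"zero probability for {aa!r} at {POSITION_LABELS[j]}")
            return -math.inf
        total += math.log2(p)
    return total


def score_peptides(pwm: PWM, peptides: list[str]) -> np.ndarray:
    """Vectorized :func:`score_peptide` over many peptides."""
    with np.errstate(divide="ignore"):
        logm = np.log2(pwm.matrix)
    idx = np.array([[AA_INDEX[aa] for aa in p] for p in peptides])
    return logm[idx, np.arange(PEPTIDE_LENGTH)].sum(axis=1)


def pwm_similarity(a: PWM, b: PWM) -> float:
    """Similarity between two PWMs on a 0-100 scale.

    Mean over the five columns of the Pearson correlation between the
    20-entry probability vectors, mapped from [-1, 1] to [0, 100] via
    100*(r+1)/2.  A zero-variance column contributes r = 0 (i.e. 50).
    """
    sims = []
    for j in range(PEPTIDE_LENGTH):
        x, y = a.matrix[:, j], b.matrix[:, j]
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            logger.warning("zero-variance PWM column %s: correlation treated as 0",
                           POSITION_LABELS[j])
            r = 0.0
        else:
            r = float(np.corrcoef(x, y)[0, 1])
        sims.append(100.0 * (r + 1.0) / 2.0)
    return float(np.mean(sims))


def information_content(pwm: PWM) -> np.ndarray:
    """Per-position information content in bits: log2(20) - H(column)."""
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pwm.matrix > 0, pwm.matrix * np.log2(pwm.matrix), 0.0)
    entropy = -plogp.sum(axis=0)
    return math.log2(N_AA) - entropy


def export_logo_matrix(pwm: PWM, path: str | Path) -> pd.DataFrame:
    """Write per-residue logo letter heights (probability x column IC, bits).

    The tabular output (rows = residues, columns = positions) can be fed
    directly to any stacked-letter logo renderer; the column sum equals
    the position's information content.
    """
    heights = pwm.matrix * information_content(pwm)[None, :]
    frame = pd.DataFrame(heights, index=list(AMINO_ACIDS), columns=POSITION_LABELS)
    frame.to_csv(path, sep="\t", index_label="aa")
    return frame


def write_pwm(pwm: PWM, path: str | Path) -> None:
    pwm.to_frame().to_csv(path, sep="\t", index_label="aa")


def read_pwm(path: str | Path) -> PWM:
    frame = pd.read_csv(path, sep="\t", index_col="aa")
    matrix = frame.reindex(list(AMINO_ACIDS))[POSITION_LABELS].to_numpy()
    return PWM(matrix)


def nearest_training_domain(test_domain: Domain, training: InteractionSet) -> str:
    """Training domain with the most similar binding site.

    Ties are broken toward the larger positive-peptide count, then the
    lexicographically smaller id (logged).
    """
    best: tuple[float, int, str] | None = None
    for did in training.domain_ids():
        sim = binding_site_similarity(test_domain, training.domains[did])
        n_pos = len(training.unique_peptides(did))
        key = (sim, n_pos)
        if best is None or key > (best[0], best[1]) or (
            key == (best[0], best[1]) and did < best[2]
        ):
            if best is not None and key == (best[0], best[1]):
                logger.info("nearest-neighbour tie between %s and %s: keeping %s",
                            best[2], did, min(best[2], did))
            best = (sim, n_pos, did)
    if best is None:
        raise ValueError("training set has no domains")
    return best[2]


def pwm_ensemble_predict(
    test_domain: Domain,
    training: InteractionSet,
    tails: dict[str, list[str]],
    top_fraction: float = 0.01,
) -> list[tuple[str, float]]:
    """Nearest-neighbour PWM baseline: scan tails with the neighbour's PWM.

    Builds a PWM from the positive peptides of the training domain most
    similar to ``test_domain``, scores every unique tail, and returns
    the top ``ceil(top_fraction * N)`` (tail, score) pairs, best first.
    Ties at the boundary are resolved by score then lexicographic tail.
    """
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    neighbour = nearest_training_domain(test_domain, training)
    positives = training.unique_peptides(neighbour)
    if not positives:
        raise ValueError(f"nearest neighbour {neighbour} has no positive peptides")
    pwm = build_pwm(positives)
    tail_list = sorted(tails)
    scores = score_peptides(pwm, tail_list)
    k = math.ceil(top_fraction * len(tail_list))
    order = sorted(range(len(tail_list)), key=lambda i: (-scores[i], tail_list[i]))
    return [(tail_list[i], float(scores[i])) for i in order[:k]]
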