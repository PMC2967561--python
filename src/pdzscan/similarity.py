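"""Sequence identity measures used for nearest-neighbour analyses.

Similarity between two aligned sequences is the fraction of positions
with identical characters.  A gap aligned to a residue counts as a
mismatch; two aligned gaps count as a match (both columns say "no
residue here" for the same alignment column).
"""

from __future__ import annotations

from .alphabet import BINDING_SITE_LENGTH, PEPTIDE_LENGTH
from .data_io import Domain


def fraction_identity(a: str, b: str) -> float:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def binding_site_similarity(a: Domain, b: Domain) -> float:
    """Fraction of matching binding-site columns between two domains."""
    if len(a.binding_site) != BINDING_SITE_LENGTH or len(b.binding_site) != BINDING_SITE_LENGTH:
        raise ValueError("binding sites must have 16 columns")
    return fraction_identity(a.binding_site, b.binding_site)


def peptide_similarity(p: str, q: str) -> float:
    """Fraction of matching residues between two 5-mer peptides."""
    if len(p) != PEPTIDE_LENGTH or len(q) != PEPTIDE_LENGTH:
        raise ValueError("peptides must have 5 residues")
    return fraction_identity(p, q)
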