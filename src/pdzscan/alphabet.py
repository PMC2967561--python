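"""Amino-acid alphabet shared by every module.

The 20 standard residues are kept in alphabetical one-letter order; this
order fixes the row order of PWMs and the bit layout of all feature
encodings, so it must never change between a trained model and the data
scored with it.
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {a: i for i, a in enumerate(AMINO_ACIDS)}
N_AA: int = 20

GAP: str = "-"

#: Residues that may appear in real proteome FASTA but carry no usable
#: side-chain identity (ambiguity codes, selenocysteine, pyrrolysine).
AMBIGUOUS: frozenset[str] = frozenset("BJOUXZ")

BINDING_SITE_LENGTH: int = 16
PEPTIDE_LENGTH: int = 5


def is_standard(residue: str) -> bool:
    """True for one of the 20 standard one-letter residue codes."""
    return residue in AA_INDEX


def check_peptide(sequence: str) -> str:
    """Validate a C-terminal 5-mer (positions p-4..p0, p0 last).

    Returns the sequence unchanged; raises ``ValueError`` on wrong
    length, gaps or non-standard residues.
    """
    if len(sequence) != PEPTIDE_LENGTH:
        raise ValueError(
            f"peptide {sequence!r} has length {len(sequence)}, expected {PEPTIDE_LENGTH}"
        )
    for ch in sequence:
        if ch not in AA_INDEX:
            raise ValueError(f"peptide {sequence!r} contains invalid residue {ch!r}")
    return sequence


def check_binding_site(sequence: str) -> str:
    """Validate a 16-column aligned PDZ binding-site sequence.

    Gap characters ('-') are allowed: binding sites come from a multiple
    alignment and may carry indels.
    """
    if len(sequence) != BINDING_SITE_LENGTH:
        raise ValueError(
            f"binding site {sequence!r} has length {len(sequence)}, "
            f"expected {BINDING_SITE_LENGTH}"
        )
    for ch in sequence:
        if ch != GAP and ch not in AA_INDEX:
            raise ValueError(
                f"binding site {sequence!r} contains invalid character {ch!r}"
            )
    return sequence
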