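"""Core domain types and file I/O for interaction tables, proteomes and
contact-map definitions.

The on-disk formats are deliberately plain: interaction tables are
tab-delimited text with a header row (``domain_id  binding_site  peptide
label  source``), proteomes are protein FASTA, and a contact map is one
``<domain position> <peptide position>`` pair per line.  Peptide positions
are written ``p-4 .. p0`` with p0 the C-terminal residue and are stored
internally as the integers -4..0.
"""

from __future__ import annotations

import logging
from collections import OrderedDict
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .alphabet import (
    BINDING_SITE_LENGTH,
    PEPTIDE_LENGTH,
    check_binding_site,
    check_peptide,
)

logger = logging.getLogger(__name__)

INTERACTION_COLUMNS = ["domain_id", "binding_site", "peptide", "label", "source"]

DEFAULT_CONTACT_MAP_RESOURCE = "contact_map_default_synthetic.txt"


@dataclass(frozen=True)
class Domain:
    """A PDZ domain represented by its aligned 16-column binding site."""

    id: str
    binding_site: str
    organism: str = ""
    source: str = "other"

    def __post_init__(self) -> None:
        check_binding_site(self.binding_site)


@dataclass(frozen=True)
class Interaction:
    """One labelled domain-peptide pair (label +1 binds / -1 does not)."""

    domain_id: str
    peptide: str
    label: int
    source: str = ""

    def __post_init__(self) -> None:
        check_peptide(self.peptide)
        if self.label not in (1, -1):
            raise ValueError(f"label must be +1 or -1, got {self.label!r}")


@dataclass
class InteractionSet:
    """An ordered collection of interactions plus the domains they reference."""

    interactions: list[Interaction] = field(default_factory=list)
    domains: dict[str, Domain] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for ia in self.interactions:
            if ia.domain_id not in self.domains:
                raise ValueError(f"interaction references unknown domain {ia.domain_id!r}")

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self) -> Iterator[Interaction]:
        return iter(self.interactions)

    @property
    def n_pos(self) -> int:
        return sum(1 for ia in self.interactions if ia.label == 1)

    @property
    def n_neg(self) -> int:
        return sum(1 for ia in self.interactions if ia.label == -1)

    def domain_ids(self) -> list[str]:
        """Domain ids in first-appearance order over the interactions."""
        seen: OrderedDict[str, None] = OrderedDict()
        for ia in self.interactions:
            seen.setdefault(ia.domain_id, None)
        return list(seen)

    def positives(self, domain_id: str | None = None) -> list[Interaction]:
        return [
            ia
            for ia in self.interactions
            if ia.label == 1 and (domain_id is None or ia.domain_id == domain_id)
        ]

    def unique_peptides(self, domain_id: str | None = None, label: int | None = 1) -> list[str]:
        """Unique peptide sequences, in first-appearance order."""
        seen: OrderedDict[str, None] = OrderedDict()
        for ia in self.interactions:
            if domain_id is not None and ia.domain_id != domain_id:
                continue
            if label is not None and ia.label != label:
                continue
            seen.setdefault(ia.peptide, None)
        return list(seen)

    def subset(self, keep: Iterable[Interaction]) -> "InteractionSet":
        keep = list(keep)
        ids = {ia.domain_id for ia in keep}
        return InteractionSet(keep, {d: self.domains[d] for d in ids})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (ia.domain_id, self.domains[ia.domain_id].binding_site, ia.peptide, ia.label, ia.source)
                for ia in self.interactions
            ],
            columns=INTERACTION_COLUMNS,
        )


@dataclass(frozen=True)
class ContactMapDef:
    """The fixed set of (domain position, peptide position) contact pairs.

    Domain positions are 1-based alignment columns 1..16; peptide
    positions are -4..0 (p0 = C-terminus).  Pair order is significant:
    it fixes the block layout of the contact-map feature encoding.
    """

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("contact map contains duplicate pairs")
        for dpos, ppos in self.pairs:
            if not 1 <= dpos <= BINDING_SITE_LENGTH:
                raise ValueError(f"domain position {dpos} outside 1..{BINDING_SITE_LENGTH}")
            if not -(PEPTIDE_LENGTH - 1) <= ppos <= 0:
                raise ValueError(f"peptide position {ppos} outside p-4..p0")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def domain_positions(self) -> set[int]:
        return {d for d, _ in self.pairs}

    @property
    def peptide_positions(self) -> set[int]:
        return {p for _, p in self.pairs}


def _parse_peptide_position(token: str) -> int:
    """Parse 'p0' / 'p-3' (or a bare integer) into -4..0."""
    tok = token.lower().lstrip("p")
    try:
        return int(tok)
    except ValueError as exc:
        raise ValueError(f"cannot parse peptide position {token!r}") from exc


def load_contact_map(path: str | Path) -> ContactMapDef:
    """Read a contact-map definition: one ``dpos ppos`` pair per line.

    Lines starting with '#' and blank lines are ignored.
    """
    pairs: list[tuple[int, int]] = []
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 fields, got {len(fields)}")
        pairs.append((int(fields[0]), _parse_peptide_position(fields[1])))
    return ContactMapDef(tuple(pairs))


def default_contact_map() -> ContactMapDef:
    """The shipped 38-pair contact-map definition.

    A synthetic reconstruction of the alpha1-syntrophin-derived map (the
    exact published pairs are not public); it preserves the structural
    constants every downstream computation depends on: 38 unique pairs,
    16 distinct domain positions, all 5 peptide positions.
    """
    ref = resources.files("pdzscan.data") / DEFAULT_CONTACT_MAP_RESOURCE
    with resources.as_file(ref) as path:
        return load_contact_map(path)


def read_interactions(path: str | Path) -> InteractionSet:
    """Parse a tab-delimited interaction table into an :class:`InteractionSet`.

    Duplicate (domain, peptide, label) rows are dropped with a warning.
    Malformed rows raise ``ValueError`` naming the offending line.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in INTERACTION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")

    domains: dict[str, Domain] = {}
    interactions: list[Interaction] = []
    seen: set[tuple[str, str, int]] = set()
    for row in df.itertuples(index=True):
        lineno = row.Index + 2  # header is line 1
        try:
            label = int(row.label)
            ia = Interaction(str(row.domain_id), str(row.peptide), label, str(row.source))
            site = check_binding_site(str(row.binding_site))
        except ValueError as exc:
            raise ValueError(f"{path}: line {lineno}: {exc}") from exc
        if ia.domain_id in domains:
            if domains[ia.domain_id].binding_site != site:
                raise ValueError(
                    f"{path}: line {lineno}: domain {ia.domain_id!r} redefined "
                    f"with a different binding site"
                )
        else:
            domains[ia.domain_id] = Domain(ia.domain_id, site)
        key = (ia.domain_id, ia.peptide, ia.label)
        if key in seen:
            logger.warning("%s: line %d: duplicate interaction %s dropped", path, lineno, key)
            continue
        seen.add(key)
        interactions.append(ia)
    return InteractionSet(interactions, domains)


def write_interactions(data: InteractionSet, path: str | Path) -> None:
    """Write an interaction table in the canonical tab-delimited form."""
    data.to_frame().to_csv(path, sep="\t", index=False)


def extract_cterminal_tails(
    proteome: str | Path, k: int = PEPTIDE_LENGTH
) -> dict[str, list[str]]:
    """Map each unique C-terminal k-mer of a protein FASTA to its protein ids.

    Trailing stop characters ('*') are stripped before the suffix is
    taken; sequences shorter than ``k`` after stripping are skipped with
    a warning.
    """
    tails: dict[str, list[str]] = {}
    n_records = 0
    for record in SeqIO.parse(str(proteome), "fasta"):
        n_records += 1
        seq = str(record.seq).rstrip("*")
        if len(seq) < k:
            logger.warning("sequence %s shorter than %d residues; skipped", record.id, k)
            continue
        tails.setdefault(seq[-k:], []).append(record.id)
    if n_records == 0:
        logger.warning("%s: empty FASTA, no tails extracted", proteome)
    return tails


def write_predictions(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a prediction table (domain_id, peptide, score, label, protein ids)."""
    frame.to_csv(path, sep="\t", index=False)
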