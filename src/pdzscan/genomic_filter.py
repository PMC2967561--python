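"""Genomic-likeness classification and enrichment filtering.

Phage display selects optimal binders that need not exist in any real
proteome.  To train a predictor of *genomic* interactions, peptides are
classed as genomic-like when their last four residues (p-3..p0) match
the C-terminal tail of a real protein, domains are categorized by how
many unique genomic-like vs non-genomic-like peptides they bind, and
the positive-only phage data are filtered to enrich for genomic-like
interactions.
"""

from __future__ import annotations

import logging
from enum import Enum

from .data_io import InteractionSet

logger = logging.getLogger(__name__)

#: Unique-peptide count at or above which a class of peptides is
#: considered "specific" for a domain.
CATEGORY_THRESHOLD = 10


class DomainCategory(Enum):
    GENOMIC_LIKE = "genomic_like"
    NON_GENOMIC_LIKE = "non_genomic_like"
    DUAL = "dual"
    NON_SPECIFIC = "non_specific"


def build_suffix_index(tails, k: int = 4) -> frozenset:
    """The set of length-``k`` suffixes of the tail keys.

    ``tails`` is either a tail map (tail -> protein ids) or any iterable
    of tail strings; every tail must have length >= k.
    """
    keys = tails.keys() if hasattr(tails, "keys") else tails
    index = set()
    for t in keys:
        if len(t) < k:
            raise ValueError(f"tail {t!r} shorter than k={k}")
        index.add(t[-k:])
    return frozenset(index)


def is_genomic_like(peptide: str, tails) -> bool:
    """True iff the peptide's last four residues match some protein tail.

    ``tails`` may be a tail map, an iterable of tails, or a precomputed
    :func:`build_suffix_index` result (recommended inside loops).
    """
    if not isinstance(tails, frozenset):
        tails = build_suffix_index(tails, k=4)
    return peptide[-4:] in tails


def categorize_domain(
    n_genomic: int, n_non_genomic: int, threshold: int = CATEGORY_THRESHOLD
) -> DomainCategory:
    """Category from the counts of unique genomic-like / non-genomic-like peptides.

    (>=t, <t) -> genomic-like; (<t, >=t) -> non-genomic-like;
    (>=t, >=t) -> dual; (<t, <t) -> non-specific.
    """
    if n_genomic < 0 or n_non_genomic < 0:
        raise ValueError("counts must be non-negative")
    g, n = n_genomic >= threshold, n_non_genomic >= threshold
    if g and not n:
        return DomainCategory.GENOMIC_LIKE
    if n and not g:
        return DomainCategory.NON_GENOMIC_LIKE
    if g and n:
        return DomainCategory.DUAL
    return DomainCategory.NON_SPECIFIC


def enrich_genomic_like(
    data: InteractionSet, tails, min_peptides: int = CATEGORY_THRESHOLD
) -> InteractionSet:
    """Filter positive-only data to enrich for genomic-like interactions.

    Rules, applied in order on categories assigned from the unfiltered
    data:

    1. drop every interaction of non-genomic-like domains;
    2. from dual domains, remove the non-genomic-like interactions;
    3. drop dual domains left with fewer than ``min_peptides`` unique
       genomic-like peptides after that removal;
    4. keep genomic-like and non-specific domains unfiltered provided
       they have at least ``min_peptides`` unique peptides in total.

    Raises ``ValueError`` if negative labels are present: the filter is
    defined for positive-only (phage display) data.
    """
    if any(ia.label == -1 for ia in data):
        raise ValueError("enrich_genomic_like requires positive-only data")
    index = build_suffix_index(tails, k=4)

    kept = []
    for domain_id in data.domain_ids():
        peptides = data.unique_peptides(domain_id)
        genomic = [p for p in peptides if is_genomic_like(p, index)]
        category = categorize_domain(len(genomic), len(peptides) - len(genomic))
        rows = [ia for ia in data if ia.domain_id == domain_id]
        if category is DomainCategory.NON_GENOMIC_LIKE:
            logger.info("domain %s is non-genomic-like: %d interactions dropped",
                        domain_id, len(rows))
            continue
        if category is DomainCategory.DUAL:
            rows = [ia for ia in rows if is_genomic_like(ia.peptide, index)]
            if len({ia.peptide for ia in rows}) < min_peptides:
                logger.info("dual domain %s below %d genomic-like peptides after "
                            "filtering: dropped", domain_id, min_peptides)
                continue
        elif len(peptides) < min_peptides:
            logger.info("domain %s has %d unique peptides (< %d): dropped",
                        domain_id, len(peptides), min_peptides)
            continue
        kept.extend(rows)
    return data.subset(kept)
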