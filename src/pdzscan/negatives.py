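"""Artificial negative interactions for positive-only (phage display) data.

Binary training needs non-binders, but phage display reports binders
only.  The principal method scores the cross-domain pool of real
positive peptides with the domain's own PWM and greedily accepts, in
ascending score order, peptides scoring strictly below the worst
positive, rejecting candidates too similar (pairwise positional
identity) to already-accepted negatives.  Three baseline strategies
(random residues, shuffled positives, random selection from the same
candidate pool) are provided for comparison.
"""

from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, check_peptide
from .data_io import Domain, Interaction
from .pwm import build_pwm, score_peptides

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NegativeConfig:
    """Parameters of artificial-negative generation.

    ``ratio`` is the requested negatives-per-positive multiple (default
    2.0, the approximate ratio of artificial negatives to phage-display
    positives used in training).  ``redundancy_max_identity`` is the
    maximum number of identical positions (of 5) allowed between any
    two selected negatives.
    """

    method: str = "pwm_selected"
    ratio: float = 2.0
    redundancy_max_identity: int = 3
    seed: int = 0
    pseudocount: float = 0.01

    def __post_init__(self) -> None:
        if self.method not in ("pwm_selected", "random", "shuffled", "randomly_selected"):
            raise ValueError(f"unknown negative-generation method {self.method!r}")
        if self.ratio <= 0:
            raise ValueError("ratio must be > 0")
        if not 0 <= self.redundancy_max_identity <= 5:
            raise ValueError("redundancy_max_identity must be in 0..5")


@dataclass
class GeneratedNegatives:
    """Negatives for one domain plus an exhaustion flag.

    ``insufficient`` is True when the candidate pool could not supply
    the requested count; such domains feed the training-data exclusion
    rule for domains that are hard to generate negatives for.
    """

    domain_id: str
    interactions: list[Interaction] = field(default_factory=list)
    insufficient: bool = False

    def __len__(self) -> int:
        return len(self.interactions)

    def __iter__(self):
        return iter(self.interactions)


def _identity_count(p: str, q: str) -> int:
    return sum(a == b for a, b in zip(p, q))


def _domain_rng(config: NegativeConfig, domain_id: str) -> np.random.Generator:
    # independent, reproducible stream per (seed, domain)
    return np.random.default_rng(
        (config.seed * 2654435761 + zlib.crc32(domain_id.encode())) % (2**31)
    )


def _candidate_pool(
    domain: Domain, positives: list[str], pool: list[str], config: NegativeConfig
) -> tuple[list[str], np.ndarray]:
    """Candidates scoring strictly below the minimum positive PWM score.

    Returned in ascending score order (ties broken lexicographically),
    with the domain's own positives excluded.
    """
    pwm = build_pwm(positives, pseudocount=config.pseudocount)
    cutoff = float(score_peptides(pwm, positives).min())
    own = set(positives)
    unique_pool = sorted(set(pool) - own)
    if not unique_pool:
        return [], np.empty(0)
    scores = score_peptides(pwm, unique_pool)
    below = [(s, p) for s, p in zip(scores, unique_pool) if s < cutoff]
    below.sort()
    return [p for _, p in below], np.array([s for s, _ in below])


def generate_negatives(
    domain: Domain,
    positives: list[str],
    pool: list[str],
    config: NegativeConfig,
) -> GeneratedNegatives:
    """Generate label -1 interactions for one domain.

    ``pool`` is the set of unique positive peptides across all domains
    (used by ``pwm_selected`` and ``randomly_selected``; ignored by the
    other methods).  The requested count is ``ceil(ratio * len(positives))``.
    """
    if not positives:
        raise ValueError("cannot generate negatives without positives")
    for p in positives:
        check_peptide(p)
    n_wanted = math.ceil(config.ratio * len(positives))
    rng = _domain_rng(config, domain.id)
    source = f"artificial_{config.method}"

    selected: list[str] = []
    insufficient = False

    if config.method == "random":
        alphabet = list(AMINO_ACIDS)
        selected = ["".join(rng.choice(alphabet, size=5)) for _ in range(n_wanted)]
    elif config.method == "shuffled":
        for i in range(n_wanted):
            residues = list(positives[i % len(positives)])
            rng.shuffle(residues)
            selected.append("".join(residues))
    else:
        candidates, _ = _candidate_pool(domain, positives, pool, config)
        if config.method == "randomly_selected":
            take = min(n_wanted, len(candidates))
            selected = list(rng.choice(candidates, size=take, replace=False))
        else:  # pwm_selected: greedy ascending-score, low-redundancy acceptance
            for cand in candidates:
                if len(selected) == n_wanted:
                    break
                if all(
                    _identity_count(cand, acc) <= config.redundancy_max_identity
                    for acc in selected
                ):
                    selected.append(cand)
        if len(selected) < n_wanted:
            insufficient = True
            logger.warning(
                "domain %s: only %d of %d requested %s negatives available",
                domain.id, len(selected), n_wanted, config.method,
            )

    interactions = [Interaction(domain.id, p, -1, source) for p in selected]
    return GeneratedNegatives(domain.id, interactions, insufficient)


def augment_with_negatives(
    data, config: NegativeConfig, drop_insufficient: bool = True
):
    """Add artificial negatives to a positive-only interaction set.

    Returns ``(training_set, per_domain)`` where ``training_set`` is the
    input positives plus generated negatives and ``per_domain`` maps
    domain id to its :class:`GeneratedNegatives`.  Domains whose
    candidate pool could not supply the requested count are excluded
    from the training set when ``drop_insufficient`` (they are the
    domains "difficult to generate artificial negatives for").
    """
    if any(ia.label == -1 for ia in data):
        raise ValueError("augment_with_negatives expects positive-only data")
    pool = data.unique_peptides()
    per_domain: dict[str, GeneratedNegatives] = {}
    kept = []
    for did in data.domain_ids():
        own = data.unique_peptides(did)
        negs = generate_negatives(data.domains[did], own, pool, config)
        if negs.insufficient and drop_insufficient:
            logger.warning("domain %s excluded: insufficient negatives", did)
            continue
        per_domain[did] = negs
        kept.extend(ia for ia in data if ia.domain_id == did)
        kept.extend(negs.interactions)
    return data.subset(kept), per_domain


def negatives_report(sets: dict[str, GeneratedNegatives | list]) -> "pd.DataFrame":
    """Per-domain and total counts of generated negatives."""
    import pandas as pd

    rows = [(did, len(negs)) for did, negs in sets.items()]
    frame = pd.DataFrame(rows, columns=["domain_id", "n_negatives"])
    if len(frame):
        total = pd.DataFrame([("TOTAL", int(frame["n_negatives"].sum()))],
                             columns=frame.columns)
        frame = pd.concat([frame, total], ignore_index=True)
    return frame
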