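"""Synthetic domain-peptide interaction data with planted structure.

The generator emulates the statistical shape of the experimental data
this kind of predictor is trained on: a family of domains, each with a
16-column binding site and a planted position-specific binding
preference over the five C-terminal ligand positions; positive peptides
sampled from that preference; decoy tails standing in for the proteome;
and optional label noise.  Binding sites and specificities are mutated
*jointly* along a family tree, so binding-site similarity between
domains predicts specificity similarity — the property the
similarity-stratified evaluation analyses depend on.

Planted specificities are independent per-position categorical
distributions (exactly the PWM model): positional dependencies are
deliberately not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .alphabet import AMINO_ACIDS, BINDING_SITE_LENGTH, N_AA, PEPTIDE_LENGTH
from .data_io import Domain, Interaction, InteractionSet


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the generator.

    ``specificity_sharpness`` s sets the preferred-residue probability
    p = s/(s+19) at each ligand position (s = inf gives a consensus-only
    domain; the default s = 40 gives p ~ 0.68, a moderately specific
    domain).  ``family_tree`` optionally fixes, per non-founder domain,
    (parent index, number of binding-site mutations); when absent a
    random chain with 1-8 mutations per child is grown from
    ``n_founders`` unrelated founders.  ``genomic_tail_fraction`` is
    the fraction of positive peptides that also appear as proteome
    tails (peptides left out model non-genomic phage-display binders).
    """

    n_domains: int = 20
    peptides_per_domain: int = 20
    specificity_sharpness: float = 40.0
    label_noise: float = 0.0
    n_decoy_tails: int = 1000
    negatives_per_positive: float = 2.0
    genomic_tail_fraction: float = 1.0
    n_founders: int = 4
    family_tree: tuple[tuple[int | None, int], ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_domains, self.peptides_per_domain, self.n_decoy_tails) <= 0:
            raise ValueError("counts must be positive")
        if not 0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must lie in [0, 0.5)")
        if not 0 <= self.genomic_tail_fraction <= 1:
            raise ValueError("genomic_tail_fraction must lie in [0, 1]")
        if self.specificity_sharpness <= 0:
            raise ValueError("specificity_sharpness must be > 0")


@dataclass
class SyntheticDataset:
    """A generated dataset plus its ground truth."""

    interactions: InteractionSet
    tails: dict[str, list[str]]
    specificities: dict[str, np.ndarray]  # domain id -> 20x5 column-stochastic


#: residues per position carrying the non-preferred probability mass;
#: real specificity columns tolerate a handful of residues, not all 20
N_TOLERATED = 4


def _spec_matrix(preferred: np.ndarray, sharpness: float) -> np.ndarray:
    matrix = np.zeros((N_AA, PEPTIDE_LENGTH))
    cols = np.arange(PEPTIDE_LENGTH)
    if math.isinf(sharpness):
        matrix[preferred, cols] = 1.0
        return matrix
    p_major = sharpness / (sharpness + N_AA - 1)
    # tolerated set is a deterministic function of the preferred residue,
    # so jointly mutated sites and preferences stay smoothly coupled
    for k in range(1, N_TOLERATED + 1):
        matrix[(preferred + k) % N_AA, cols] = (1.0 - p_major) / N_TOLERATED
    matrix[preferred, cols] = p_major
    return matrix


def _sample_peptide(spec: np.ndarray, rng: np.random.Generator) -> str:
    return "".join(
        AMINO_ACIDS[rng.choice(N_AA, p=spec[:, j])] for j in range(PEPTIDE_LENGTH)
    )


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a labelled interaction set, a tail map and ground truth.

    Fully determined by ``config.seed``: positives are drawn from each
    domain's planted specificity, negatives are decoy tails, and each
    label is flipped with probability ``label_noise``.
    """
    rng = np.random.default_rng(config.seed)
    aa = np.array(list(AMINO_ACIDS))

    tree = config.family_tree
    if tree is not None and len(tree) != config.n_domains:
        raise ValueError("family_tree must list one entry per domain")

    sites: list[np.ndarray] = []
    preferred: list[np.ndarray] = []
    for i in range(config.n_domains):
        if tree is not None:
            parent, n_mut = tree[i]
        else:
            parent = None if i < config.n_founders else int(rng.integers(0, i))
            n_mut = int(rng.integers(1, 9))
        if parent is None:
            sites.append(rng.integers(0, N_AA, size=BINDING_SITE_LENGTH))
            preferred.append(rng.integers(0, N_AA, size=PEPTIDE_LENGTH))
            continue
        if not 0 <= parent < i:
            raise ValueError(f"domain {i}: parent index {parent} must precede it")
        if not 0 <= n_mut <= BINDING_SITE_LENGTH:
            raise ValueError(f"domain {i}: cannot mutate {n_mut} of "
                             f"{BINDING_SITE_LENGTH} site positions")
        site = sites[parent].copy()
        pref = preferred[parent].copy()
        mut_pos = rng.choice(BINDING_SITE_LENGTH, size=n_mut, replace=False)
        for pos in mut_pos:
            site[pos] = (site[pos] + 1 + rng.integers(0, N_AA - 1)) % N_AA
            # joint site/specificity drift keeps the site->specificity map smooth
            if rng.random() < 0.5:
                j = int(rng.integers(0, PEPTIDE_LENGTH))
                pref[j] = int(rng.integers(0, N_AA))
        sites.append(site)
        preferred.append(pref)

    domains: dict[str, Domain] = {}
    specs: dict[str, np.ndarray] = {}
    for i in range(config.n_domains):
        did = f"SYND-{i:03d}"
        domains[did] = Domain(did, "".join(aa[sites[i]]), organism="synthetic",
                              source="microarray")
        specs[did] = _spec_matrix(preferred[i], config.specificity_sharpness)

    positives: dict[str, list[str]] = {
        did: [_sample_peptide(specs[did], rng) for _ in range(config.peptides_per_domain)]
        for did in domains
    }

    # decoy proteome tails, plus the genomic fraction of positive peptides
    tails: dict[str, list[str]] = {}
    for i in range(config.n_decoy_tails):
        tail = "".join(aa[rng.integers(0, N_AA, size=PEPTIDE_LENGTH)])
        tails.setdefault(tail, []).append(f"decoy_{i:05d}")
    for did, peps in positives.items():
        for k, pep in enumerate(peps):
            if rng.random() < config.genomic_tail_fraction:
                tails.setdefault(pep, []).append(f"src_{did}_{k}")

    interactions: list[Interaction] = []
    decoy_pool = sorted(tails)
    for did, peps in positives.items():
        own = set(peps)
        for pep in peps:
            interactions.append(Interaction(did, pep, 1, "synthetic"))
        n_neg = math.ceil(config.negatives_per_positive * len(peps))
        candidates = [t for t in decoy_pool if t not in own]
        chosen = rng.choice(candidates, size=min(n_neg, len(candidates)), replace=False)
        for tail in chosen:
            interactions.append(Interaction(did, str(tail), -1, "synthetic"))

    if config.label_noise > 0:
        flips = rng.random(len(interactions)) < config.label_noise
        interactions = [
            Interaction(ia.domain_id, ia.peptide, -ia.label if flip else ia.label,
                        ia.source)
            for ia, flip in zip(interactions, flips)
        ]

    return SyntheticDataset(InteractionSet(interactions, domains), tails, specs)


def generate_positive_only_view(dataset: SyntheticDataset) -> InteractionSet:
    """Drop negative labels, emulating positive-only phage-display data."""
    data = dataset.interactions
    return data.subset([ia for ia in data if ia.label == 1])


def write_proteome_fasta(
    tails: dict[str, list[str]], path, seed: int = 0, prefix_length: int = 20
) -> None:
    """Write a protein FASTA whose record suffixes reproduce the tail map."""
    rng = np.random.default_rng(seed)
    aa = np.array(list(AMINO_ACIDS))
    with open(path, "w") as fh:
        for tail in sorted(tails):
            for pid in tails[tail]:
                prefix = "".join(aa[rng.integers(0, N_AA, size=prefix_length)])
                fh.write(f">{pid}\n{prefix}{tail}\n")
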