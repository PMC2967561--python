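import numpy as np
import pytest

from pdzscan.data_io import Domain, Interaction, InteractionSet
from pdzscan.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_domain():
    return Domain("TOY-1", "ACDEFGHIKLMNPQRS")


@pytest.fixture
def toy_domains():
    return [
        Domain("TOY-1", "ACDEFGHIKLMNPQRS"),
        Domain("TOY-2", "ACDEFGHIKLMNPQRT"),
        Domain("TOY-3", "WWWWWWWWWWWWWWWW"),
    ]


@pytest.fixture
def small_dataset():
    """12 domains x 15 peptides, noise-free, with decoy negatives."""
    return generate_dataset(
        SyntheticConfig(n_domains=12, peptides_per_domain=15,
                        n_decoy_tails=400, seed=42)
    )


def make_interaction_set(rows):
    """Build an InteractionSet from (domain_id, site, peptide, label) tuples."""
    domains = {}
    interactions = []
    for domain_id, site, peptide, label in rows:
        domains.setdefault(domain_id, Domain(domain_id, site))
        interactions.append(Interaction(domain_id, peptide, label))
    return InteractionSet(interactions, domains)
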