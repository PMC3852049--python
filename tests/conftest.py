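import random

import pytest

from netcoal import (
    SimConfig,
    parse_gene_tree,
    parse_network,
    parse_species_tree,
    random_network,
    random_species_tree,
    simulate_gene_tree,
)


@pytest.fixture
def tree3():
    """Three-taxon species tree with internal branch of 1 coalescent unit."""
    return parse_species_tree("((A:1,B:1):1,C:2);")


@pytest.fixture
def gene_match():
    return parse_gene_tree("((A,B),C);")


@pytest.fixture
def gene_disc():
    return parse_gene_tree("((A,C),B);")


@pytest.fixture
def diamond():
    """One-reticulation diamond: hybrid species X with parents near A and C."""
    return parse_network("((A:1,(X:0.5)#H1:0.5::0.3):1,(#H1:0.5::0.7,C:1):1);")


def random_instance(rng: random.Random, ntaxa: int, q: int, with_lengths=True):
    """One random network plus one gene tree simulated inside it."""
    S = random_species_tree(ntaxa, rng.uniform(1.5, 4.0), rng.randrange(1 << 30))
    for e in list(S.length):
        S.length[e] = rng.uniform(0.2, 5.0)
    N = random_network(S, q, rng.randrange(1 << 30)) if q else S
    for e in list(N.length):
        if N.length[e] == 0.0:
            N.length[e] = 0.1
    g, mu = simulate_gene_tree(N, SimConfig(seed=rng.randrange(1 << 30)))
    return N, g, mu
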