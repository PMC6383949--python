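import numpy as np
import pytest

from gridgwas import ModelSpec, additive_kinship
from gridgwas.kinships import RelationshipMatrix, normalize_kinship
from gridgwas.simulate import simulate_phenotype, simulate_structured_genotypes


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_psd_kinship(rng, n, normalized=True):
    A = rng.standard_normal((n, n))
    K = RelationshipMatrix([f"s{i}" for i in range(n)], A @ A.T / n)
    return normalize_kinship(K) if normalized else K


@pytest.fixture
def small_kinship(rng):
    return random_psd_kinship(rng, 25)


@pytest.fixture(scope="session")
def family_population():
    """Structured genotypes + additive kinship shared across tests."""
    G = simulate_structured_genotypes(150, 400, blocks=10, seed=11)
    K = additive_kinship(G)
    return G, K


@pytest.fixture(scope="session")
def single_re_spec(family_population):
    """One-random-effect model with a moderate causal marker."""
    G, K = family_population
    y, truth = simulate_phenotype(
        [K], (0.5,), marker=G.dosages[:, 3], effect_fraction=0.08, seed=12
    )
    spec = ModelSpec(y, np.ones((G.n, 1)), None, [(None, K)])
    return spec, G, truth
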