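import numpy as np
import pytest

from fourbase import SimParams, default_toy_structure, simulate_reads


@pytest.fixture(scope="session")
def toy_structure():
    return default_toy_structure()


@pytest.fixture(scope="session")
def toy_simulation(toy_structure):
    """A moderate single-state read set with truth, shared across tests."""
    params = SimParams(structures=[toy_structure])
    reads, truth = simulate_reads(params, 20000, seed=11)
    return params, reads, truth


@pytest.fixture(scope="session")
def toy_sim_100k(toy_structure):
    """100k single-state reads at default chemistry, for rate-convergence
    and filter-discrimination checks."""
    params = SimParams(structures=[toy_structure])
    reads, truth = simulate_reads(params, 100_000, seed=21)
    return params, reads, truth


@pytest.fixture(scope="session")
def planted_simulation(toy_structure):
    """300k reads from a two-state ensemble with an 8-bp helix open in
    half the molecules; shared by PAIR recovery tests."""
    from fourbase import planted_helix_ensemble

    helix = [p for p in toy_structure.pairs() if 4 <= p[0] <= 11]
    params = planted_helix_ensemble(toy_structure, helix, 0.5)
    reads, truth = simulate_reads(params, 300_000, seed=101)
    return params, helix, reads, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
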