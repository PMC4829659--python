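import numpy as np
import pytest

import trophodiv as td


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20231)


@pytest.fixture(scope="session")
def small_tree():
    return td.read_newick("((A:1.0,B:1.0):1.0,(C:1.5,D:1.5):0.5);")


@pytest.fixture(scope="session")
def bd_params():
    return td.MusseParameters([0.4], [0.1], [[0.0]])


def random_yule_tree(n_tips, seed, lam=1.0):
    """Pure-birth tree used widely as a neutral topology fixture."""
    p = td.MusseParameters([lam], [0.0], [[0.0]])
    tree, _ = td.simulate_musse_tree(
        td.SimulationConfig(p, n_tips=n_tips, root_state=0, seed=seed))
    return tree


def simulate_surviving(p, seed, **kwargs):
    """Simulate a tree, skipping seeds whose stem lineage dies out."""
    for attempt in range(200):
        try:
            return td.simulate_musse_tree(
                td.SimulationConfig(p, seed=seed + 1009 * attempt, **kwargs))
        except td.TotalExtinctionError:
            continue
    raise RuntimeError("no surviving simulation in 200 attempts")


@pytest.fixture(scope="session")
def yule_200():
    return random_yule_tree(200, seed=77)
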