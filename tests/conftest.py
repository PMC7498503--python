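import numpy as np
import pytest

import morphorep as mr
from morphorep.swc import Morphology


@pytest.fixture(scope="session")
def toys():
    return mr.toy_fixtures()


def random_tree(rng: np.random.Generator, n_nodes: int = 20) -> Morphology:
    """Random tree topology with random embedding (may multifurcate)."""
    kind = [1]
    xyz = [np.zeros(3)]
    radius = [2.0]
    parent = [-1]
    for i in range(1, n_nodes):
        p = int(rng.integers(i))
        kind.append(2)
        xyz.append(xyz[p] + rng.normal(0, 3, 3))
        radius.append(0.5)
        parent.append(p)
    return Morphology(np.arange(1, n_nodes + 1), np.array(kind),
                      np.array(xyz), np.array(radius), np.array(parent))


@pytest.fixture(scope="session")
def random_trees():
    rng = np.random.default_rng(2024)
    return [random_tree(rng, int(rng.integers(5, 40))) for _ in range(50)]


@pytest.fixture(scope="session")
def small_population():
    """One small planted-difference population shared across CV tests."""
    spec = mr.synthetic.default_population_spec(seed=11, n_cells=8)
    cells, manifest = mr.generate_population(spec)
    return cells, manifest
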