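import numpy as np
import pytest
from hypothesis import settings

from florashift.community import SpatialHierarchy
from florashift.synthetic import SimulationConfig, generate_dataset, simulate_tree
from florashift.tree import parse_newick

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_tree():
    """((A:1,B:1):1,C:2); — the worked example tree."""
    return parse_newick("((A:1.0,B:1.0):1.0,C:2.0);")


@pytest.fixture(scope="session")
def toy_hierarchy():
    return SpatialHierarchy(
        {"c1": "r1", "c2": "r1", "c3": "r2"},
        {"r1": "Europe", "r2": "Africa"},
    )


@pytest.fixture(scope="session")
def default_dataset():
    """The standard synthetic study design (200 sp, 5 × 2 × 10 cells)."""
    return generate_dataset(SimulationConfig(seed=11))


def random_instance(rng: np.random.Generator, max_tips=12, max_cells=6):
    """Small random tree + assemblages for oracle-equivalence checks."""
    n = int(rng.integers(4, max_tips + 1))
    tree = simulate_tree(
        SimulationConfig(n_species=n, seed=int(rng.integers(2**31 - 1)))
    )
    n_cells = int(rng.integers(2, max_cells + 1))
    cells = []
    for _ in range(n_cells):
        k = int(rng.integers(1, n + 1))
        cells.append(
            frozenset(str(s) for s in rng.choice(tree.tip_labels, k, replace=False))
        )
    return tree, cells
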