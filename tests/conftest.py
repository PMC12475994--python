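import numpy as np
import pytest

from gmnet import build_network, generate_cohort
from gmnet.synthetic import CohortConfig


@pytest.fixture(scope="session")
def small_cohort():
    """30 subjects (10/group), 90 ROIs, reduced voxel counts."""
    config = CohortConfig(
        group_sizes={"HC": 10, "DM": 10, "DKD": 10},
        voxels_per_roi=(80, 160),
        seed=11,
    )
    cohort, subjects = generate_cohort(config)
    return config, cohort, subjects


@pytest.fixture(scope="session")
def small_cohort_networks(small_cohort):
    _, cohort, subjects = small_cohort
    return cohort, [build_network(s) for s in subjects]


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_graph_adjacency(rng, n, p=0.5, weighted=True, ensure_edge=True):
    """Random symmetric adjacency used across oracle-comparison tests."""
    a = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(len(iu)) < p
    if ensure_edge and not present.any():
        present[0] = True
    w = rng.uniform(0.1, 1.0, len(iu)) if weighted else np.ones(len(iu))
    a[iu[present], ju[present]] = w[present]
    a[ju[present], iu[present]] = w[present]
    return a
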