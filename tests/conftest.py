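import numpy as np
import pytest

from trajstates import SimulationSpec, TrajectorySet, generate_trajectory


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def three_cluster_traj():
    """One trajectory with three tight, well-separated clusters plus noise."""
    spec = SimulationSpec(
        node_locations=[(0.0, 0.0), (1.0, 0.0), (0.0, 1.0)],
        cluster_sizes=(50, 50, 50),
        path_spread=0.05,
        n_noise=15,
        noise_box=[(-2.0, 3.0), (-2.0, 3.0)],
        seed=7,
    )
    return generate_trajectory(spec)


@pytest.fixture
def small_trajectory_set(rng):
    """Two subjects moving among three well-separated locations in 2-D."""
    nodes = np.array([[0.0, 0.0], [3.0, 0.0], [0.0, 3.0]])
    data = {}
    for i, sid in enumerate(("sub-a", "sub-b")):
        idx = rng.integers(0, 3, size=60)
        data[sid] = nodes[idx] + 0.05 * rng.standard_normal((60, 2))
    return TrajectorySet(subjects=list(data), data=data)
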