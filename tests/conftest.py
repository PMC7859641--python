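import numpy as np
import pytest

import routeclust as rc


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_traj(points, traj_id="t", frame_rate=60.0, individual_id="b0"):
    return rc.Trajectory(
        traj_id=traj_id,
        positions=np.asarray(points, dtype=float),
        individual_id=individual_id,
        frame_rate=frame_rate,
    )


@pytest.fixture()
def straight_traj():
    """Constant-speed straight path along +x at y = 5 (4 mm/frame)."""
    xs = np.arange(0, 40, 4.0)
    return make_traj(np.column_stack([xs, np.full_like(xs, 5.0)]))


@pytest.fixture(scope="session")
def benchmark():
    """The canonical 4-route planted dataset (80 trajectories)."""
    return rc.default_benchmark()


@pytest.fixture(scope="session")
def benchmark_description(benchmark):
    """Similarity description of the benchmark at the reference step (s=6)."""
    tset, _ = benchmark
    resampled = rc.resample_set(tset, 6.0)
    matrices = [
        rc.pairwise_distance_matrix(resampled, m) for m in ("dtw", "frechet")
    ]
    return rc.similarity_description(matrices)


def random_walk(rng, n, scale=1.0):
    return np.cumsum(rng.normal(0.0, scale, size=(n, 2)), axis=0)
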