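import numpy as np
import pytest

import routeclust as rc
from routeclust.preprocess import ResampledTrajectory

from conftest import make_traj


def brute_dtw(a, b):
    """Memo-free enumeration of all monotone warping paths."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def d(i, j):
        return float(np.hypot(*(a[i] - b[j])))

    def cost(i, j):
        if i == 0 and j == 0:
            return d(0, 0)
        options = []
        if i > 0:
            options.append(cost(i - 1, j))
        if j > 0:
            options.append(cost(i, j - 1))
        if i > 0 and j > 0:
            options.append(cost(i - 1, j - 1))
        return d(i, j) + min(options)

    return cost(len(a) - 1, len(b) - 1)


def naive_frechet(a, b):
    """Direct recursive definition of the discrete Frechet distance."""
    a, b = np.asarray(a, float), np.asarray(b, float)

    def d(i, j):
        return float(np.hypot(*(a[i] - b[j])))

    def c(i, j):
        if i == 0 and j == 0:
            return d(0, 0)
        if i == 0:
            return max(c(0, j - 1), d(0, j))
        if j == 0:
            return max(c(i - 1, 0), d(i, 0))
        return max(min(c(i - 1, j), c(i - 1, j - 1), c(i, j - 1)), d(i, j))

    return c(len(a) - 1, len(b) - 1)


def random_pair(rng, max_len, integers=False):
    n, m = rng.integers(1, max_len + 1, size=2)
    if integers:
        return (
            rng.integers(-5, 6, size=(n, 2)).astype(float),
            rng.integers(-5, 6, size=(m, 2)).astype(float),
        )
    return rng.normal(size=(n, 2)), rng.normal(size=(m, 2))


class TestDTW:
    def test_identity(self, rng):
        a = rng.normal(size=(9, 2))
        assert rc.dtw_distance(a, a) == 0.0

    def test_two_unit_pairings(self):
        assert rc.dtw_distance([(0, 0), (1, 0)], [(0, 1), (1, 1)]) == pytest.approx(2.0)

    def test_matches_brute_force(self, rng):
        for _ in range(200):
            a, b = random_pair(rng, 7)
            assert rc.dtw_distance(a, b) == pytest.approx(brute_dtw(a, b), abs=1e-9)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            rc.dtw_distance(np.empty((0, 2)), [(0, 0)])

    def test_rigid_motion_invariant(self, rng):
        a, b = rng.normal(size=(8, 2)), rng.normal(size=(6, 2))
        theta = 1.1
        rot = np.array([[np.cos(theta), -np.sin(theta)],
                        [np.sin(theta), np.cos(theta)]])
        shift = np.array([3.0, -2.0])
        moved = rc.dtw_distance(a @ rot.T + shift, b @ rot.T + shift)
        assert moved == pytest.approx(rc.dtw_distance(a, b))


class TestFastDTW:
    def test_identity(self, rng):
        a = rng.normal(size=(40, 2))
        assert rc.fastdtw_distance(a, a) == 0.0

    def test_full_radius_equals_exact(self, rng):
        for _ in range(20):
            a, b = random_pair(rng, 30)
            r = max(len(a), len(b))
            assert rc.fastdtw_distance(a, b, radius=r) == pytest.approx(
                rc.dtw_distance(a, b), abs=1e-9
            )

    def test_upper_bounds_exact(self, rng):
        for _ in range(50):
            a, b = random_pair(rng, 40)
            assert rc.fastdtw_distance(a, b, radius=1) >= rc.dtw_distance(a, b) - 1e-9

    def test_close_on_smooth_resampled_paths(self, rng):
        # smooth paths resampled at constant steps: default radius within 5%
        for seed in range(10):
            g = np.random.default_rng(seed)
            xs = np.linspace(0, 200, 300)
            a = np.column_stack([xs, 20 * np.sin(xs / 30) + g.normal(0, 0.3, 300)])
            b = np.column_stack([xs, 20 * np.sin(xs / 30 + 0.4) + g.normal(0, 0.3, 300)])
            ra = rc.resample_equal_arclength(make_traj(a), 2.0).positions
            rb = rc.resample_equal_arclength(make_traj(b), 2.0).positions
            exact = rc.dtw_distance(ra, rb)
            approx = rc.fastdtw_distance(ra, rb, radius=10)
            assert exact <= approx <= 1.05 * exact

    def test_negative_radius_raises(self):
        with pytest.raises(ValueError):
            rc.fastdtw_distance([(0, 0)], [(0, 0)], radius=-1)


class TestFrechet:
    def test_identity(self, rng):
        a = rng.normal(size=(7, 2))
        assert rc.frechet_distance(a, a) == 0.0

    def test_parallel_offset_segments(self):
        xs = np.arange(0, 10, 1.0)
        a = np.column_stack([xs, np.zeros(10)])
        b = np.column_stack([xs, np.full(10, 3.0)])
        assert rc.frechet_distance(a, b) == pytest.approx(3.0)

    def test_matches_naive_recursion(self, rng):
        for _ in range(200):
            a, b = random_pair(rng, 8)
            assert rc.frechet_distance(a, b) == pytest.approx(
                naive_frechet(a, b), abs=1e-12
            )

    def test_endpoint_lower_bound(self, rng):
        for _ in range(50):
            a, b = random_pair(rng, 10)
            lb = max(np.hypot(*(a[0] - b[0])), np.hypot(*(a[-1] - b[-1])))
            assert rc.frechet_distance(a, b) >= lb - 1e-12

    def test_symmetry_and_triangle_inequality(self, rng):
        for _ in range(50):
            a, b = random_pair(rng, 8)
            c, _ = random_pair(rng, 8)
            dab = rc.frechet_distance(a, b)
            assert dab == pytest.approx(rc.frechet_distance(b, a))
            dac = rc.frechet_distance(a, c)
            dcb = rc.frechet_distance(c, b)
            assert dab <= dac + dcb + 1e-12


def _resampled(points, tid, step=1.0):
    return ResampledTrajectory(traj_id=tid, positions=np.asarray(points, float),
                               step_mm=step)


class TestPairwiseMatrix:
    def test_identical_paths_zero_matrix(self):
        pts = [[0, 0], [1, 0], [2, 0]]
        rs = [_resampled(pts, f"t{i}") for i in range(3)]
        dm = rc.pairwise_distance_matrix(rs, "dtw")
        np.testing.assert_array_equal(dm.values, 0.0)

    def test_symmetry_bitwise(self, rng):
        rs = [_resampled(rng.normal(size=(8, 2)), f"t{i}") for i in range(5)]
        dm = rc.pairwise_distance_matrix(rs, "frechet")
        assert np.array_equal(dm.values, dm.values.T)
        assert np.all(np.diag(dm.values) == 0.0)

    def test_planted_separation(self, rng):
        near = [_resampled(rng.normal(scale=0.1, size=(10, 2)), f"a{i}")
                for i in range(3)]
        far = [_resampled(rng.normal(scale=0.1, size=(10, 2)) + 100.0, f"b{i}")
               for i in range(3)]
        dm = rc.pairwise_distance_matrix(near + far, "dtw")
        within = [dm.values[i, j] for i in range(3) for j in range(3) if i < j]
        within += [dm.values[i, j] for i in range(3, 6) for j in range(3, 6) if i < j]
        between = [dm.values[i, j] for i in range(3) for j in range(3, 6)]
        assert max(within) < min(between)

    def test_mixed_steps_rejected(self, rng):
        rs = [
            _resampled(rng.normal(size=(5, 2)), "a", step=1.0),
            _resampled(rng.normal(size=(5, 2)), "b", step=2.0),
        ]
        with pytest.raises(ValueError, match="mixed"):
            rc.pairwise_distance_matrix(rs, "dtw")

    def test_needs_two(self, rng):
        with pytest.raises(ValueError):
            rc.pairwise_distance_matrix([_resampled(rng.normal(size=(5, 2)), "a")])


class TestSimilarityDescription:
    def _matrices(self, rng, n):
        rs = [_resampled(rng.normal(size=(8, 2)) + 5 * i, f"t{i}") for i in range(n)]
        return [rc.pairwise_distance_matrix(rs, m) for m in ("dtw", "frechet")]

    def test_two_measures_double_columns(self, rng):
        desc = rc.similarity_description(self._matrices(rng, 6))
        assert desc.values.shape == (6, 12)

    def test_single_measure_diagonal_zeros(self, rng):
        desc = rc.similarity_description(self._matrices(rng, 5)[:1])
        assert desc.values.shape == (5, 5)
        np.testing.assert_array_equal(np.diag(desc.values), 0.0)

    def test_minmax_range(self, rng):
        desc = rc.similarity_description(self._matrices(rng, 6))
        assert desc.values.min() == 0.0
        assert desc.values.max() == 1.0
        assert ((desc.values >= 0) & (desc.values <= 1)).all()

    def test_constant_matrix_rejected(self):
        dm = rc.DistanceMatrix(
            measure="dtw", values=np.zeros((3, 3)), ids=("a", "b", "c")
        )
        with pytest.raises(ValueError, match="degenerate"):
            rc.similarity_description([dm])

    def test_mismatched_ids_rejected(self, rng):
        m1 = self._matrices(rng, 4)[0]
        m2 = rc.DistanceMatrix(
            measure="frechet", values=m1.values.copy(), ids=("w", "x", "y", "z")
        )
        with pytest.raises(ValueError, match="ids"):
            rc.similarity_description([m1, m2])
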