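import numpy as np
import pytest
from scipy.spatial.distance import cdist

import routeclust as rc
from routeclust.m3c import ConsensusMatrix, pam


def blobs(rng, centers, n_per, scale=1.0):
    rows = [rng.normal(size=(n_per, len(c))) * scale + np.asarray(c, float)
            for c in centers]
    labels = np.repeat(np.arange(len(centers)), n_per)
    return np.vstack(rows), labels


def cfg(**kw):
    defaults = dict(n_consensus_iters=30, n_reference_sims=20, seed=7)
    defaults.update(kw)
    return rc.M3CConfig(**defaults)


class TestConfig:
    def test_defaults(self):
        c = rc.M3CConfig()
        assert c.k_range == tuple(range(2, 11))
        assert (c.u1, c.u2) == (0.1, 0.9)
        assert c.n_consensus_iters == c.n_reference_sims == 100
        assert c.subsample_fraction == 0.8

    @pytest.mark.parametrize(
        "kw",
        [
            {"u1": 0.9, "u2": 0.1},
            {"k_range": (1, 2)},
            {"subsample_fraction": 1.5},
            {"n_consensus_iters": 0},
        ],
    )
    def test_invalid(self, kw):
        with pytest.raises(ValueError):
            rc.M3CConfig(**kw)


class TestPAM:
    def test_recovers_separated_blobs(self, rng):
        x, truth = blobs(rng, [(0, 0), (50, 0), (0, 50)], 10)
        labels, medoids = pam(cdist(x, x), 3)
        # same partition as truth (up to label permutation)
        for c in range(3):
            assert len(set(labels[truth == c])) == 1
        assert len(set(labels)) == 3
        for m in medoids:
            assert labels[m] == np.argmin(cdist(x, x)[m, medoids])

    def test_deterministic(self, rng):
        x, _ = blobs(rng, [(0, 0), (10, 0)], 8)
        d = cdist(x, x)
        l1, m1 = pam(d, 2)
        l2, m2 = pam(d, 2)
        np.testing.assert_array_equal(l1, l2)
        np.testing.assert_array_equal(m1, m2)

    def test_k_exceeds_n(self, rng):
        x = rng.normal(size=(4, 2))
        with pytest.raises(ValueError):
            pam(cdist(x, x), 5)


class TestConsensusCluster:
    def test_separated_blobs_binary_consensus(self, rng):
        x, truth = blobs(rng, [(0, 0), (100, 0)], 10, scale=1.0)  # 20 sigma apart
        cm, labels = rc.consensus_cluster(x, 2, cfg())
        assert set(np.unique(cm.values)) <= {0.0, 1.0}
        within = cm.values[np.ix_(truth == 0, truth == 0)]
        assert (within == 1.0).all()
        for c in range(2):
            assert len(set(labels[truth == c])) == 1

    def test_bitwise_deterministic(self, rng):
        x, _ = blobs(rng, [(0, 0), (8, 0)], 8)
        cm1, l1 = rc.consensus_cluster(x, 2, cfg())
        cm2, l2 = rc.consensus_cluster(x, 2, cfg())
        assert np.array_equal(cm1.values, cm2.values)
        np.testing.assert_array_equal(l1, l2)

    def test_single_full_subsample_matches_pam(self, rng):
        x = rng.normal(size=(4, 3))
        c = cfg(n_consensus_iters=1, subsample_fraction=0.999)  # ceil -> all 4
        cm, _ = rc.consensus_cluster(x, 2, c)
        assert set(np.unique(cm.values)) <= {0.0, 1.0}
        pam_labels, _ = pam(cdist(x, x), 2)
        same = pam_labels[:, None] == pam_labels[None, :]
        np.testing.assert_array_equal(cm.values, same.astype(float))

    def test_k_too_large(self, rng):
        x = rng.normal(size=(6, 2))
        with pytest.raises(ValueError):
            rc.consensus_cluster(x, 7, cfg())

    def test_consensus_matrix_invariants(self, rng):
        x, _ = blobs(rng, [(0, 0), (5, 0), (0, 5)], 7)
        cm, labels = rc.consensus_cluster(x, 3, cfg())
        v = cm.values
        assert np.allclose(v, v.T)
        assert ((v >= 0) & (v <= 1)).all()
        assert np.allclose(np.diag(v), 1.0)
        assert len(np.unique(labels)) == 3


def consensus_from_values(values):
    v = np.asarray(values, float)
    return ConsensusMatrix(
        values=v, K=2, copair_counts=v, cosample_counts=np.ones_like(v)
    )


class TestPAC:
    def test_binary_consensus_zero(self):
        v = np.array([[1, 1, 0], [1, 1, 0], [0, 0, 1]], dtype=float)
        assert rc.pac_score(consensus_from_values(v)) == 0.0

    def test_all_half_is_one(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        assert rc.pac_score(consensus_from_values(v)) == 1.0

    def test_six_value_worked_example(self):
        # off-diagonal pairs {0.05, 0.2, 0.5, 0.85, 0.95, 1.0}; (0.1, 0.9] -> 3/6
        vals = [0.05, 0.2, 0.5, 0.85, 0.95, 1.0]
        v = np.ones((4, 4))
        iu = np.triu_indices(4, k=1)
        v[iu] = vals
        v[(iu[1], iu[0])] = vals
        assert rc.pac_score(consensus_from_values(v), 0.1, 0.9) == pytest.approx(0.5)

    def test_monotone_under_disambiguation(self, rng):
        # moving ambiguous entries outside (U1, U2] never increases PAC
        v = rng.uniform(size=(8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        before = rc.pac_score(consensus_from_values(v))
        w = v.copy()
        iu = np.triu_indices(8, k=1)
        amb = (w[iu] > 0.1) & (w[iu] <= 0.9)
        flat = w[iu]
        flat[amb] = np.where(flat[amb] > 0.5, 1.0, 0.0)[...]
        w[iu] = flat
        w[(iu[1], iu[0])] = flat
        after = rc.pac_score(consensus_from_values(w))
        assert after <= before


class TestSimulateReference:
    def test_means_match(self, rng):
        x = rng.normal(size=(40, 5)) * [1, 2, 3, 4, 5] + [10, 0, -3, 5, 1]
        refs = rc.simulate_reference(x, cfg(n_reference_sims=100))
        stacked = np.stack(refs)
        np.testing.assert_allclose(
            stacked.mean(axis=(0, 1)), x.mean(axis=0), atol=0.2
        )

    def test_pc_variances_match(self, rng):
        x = rng.normal(size=(60, 4)) * [5, 3, 1, 0.5]
        refs = rc.simulate_reference(x, cfg(n_reference_sims=100))
        _, s_obs, vt = np.linalg.svd(x - x.mean(axis=0), full_matrices=False)
        var_obs = s_obs**2 / (len(x) - 1)
        var_null = np.mean(
            [((r - r.mean(0)) @ vt.T).var(axis=0, ddof=1) for r in refs], axis=0
        )
        np.testing.assert_allclose(var_null, var_obs, rtol=0.10)

    def test_seeded_reproducible(self, rng):
        x = rng.normal(size=(10, 3))
        r1 = rc.simulate_reference(x, cfg(n_reference_sims=3))
        r2 = rc.simulate_reference(x, cfg(n_reference_sims=3))
        np.testing.assert_array_equal(r1[0], r2[0])

    def test_shape_preserved(self, rng):
        x = rng.normal(size=(12, 7))
        refs = rc.simulate_reference(x, cfg(n_reference_sims=4))
        assert len(refs) == 4
        assert all(r.shape == x.shape for r in refs)


class TestSelectK:
    def test_shape_contract(self, rng):
        x, _ = blobs(rng, [(0, 0), (30, 0)], 8)
        c = cfg(k_range=(2, 3, 4), n_reference_sims=10, n_consensus_iters=20)
        res = rc.m3c_select_k(x, c)
        assert res.ks == (2, 3, 4)
        for k in res.ks:
            assert 0.0 <= res.pac[k] <= 1.0
            assert 0.0 < res.p_values[k] <= 1.0
            assert len(res.null_pac[k]) == 10
            assert len(res.labels[k]) == 16

    def test_planted_four_routes_recovered(self, rng):
        x, truth = blobs(rng, [(0, 0), (40, 0), (0, 40), (40, 40)], 10)
        res = rc.m3c_select_k(x, cfg(n_reference_sims=30, n_consensus_iters=40))
        assert 4 in res.candidates
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth, res.labels[4]) >= 0.9

    def test_single_gaussian_mostly_unrejected(self):
        # null self-consistency: no significant K in >= 9/10 seeded runs
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).normal(size=(30, 4))
            res = rc.m3c_select_k(
                x, cfg(seed=seed, n_reference_sims=25, n_consensus_iters=25)
            )
            if not res.candidates:
                hits += 1
        assert hits >= 9

    def test_summary_frame(self, rng):
        x, _ = blobs(rng, [(0, 0), (20, 0)], 6)
        res = rc.m3c_select_k(x, cfg(k_range=(2, 3), n_reference_sims=5,
                                     n_consensus_iters=10))
        df = res.summary()
        assert list(df.columns) == ["K", "pac", "p_value", "candidate"]
        assert list(df["K"]) == [2, 3]
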