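"""Weighted clustering, path length, surrogates and normalization."""

import numpy as np
import pytest

from plinet import (
    ConnectivityMatrix,
    SmallWorldMetrics,
    measures_per_recording,
    normalized_measures,
    shuffle_surrogate,
    weighted_clustering,
    weighted_path_length,
)


def brute_force_clustering(W):
    """Independent oracle: explicit triple loop over ordered neighbor pairs."""
    n = W.shape[0]
    cis = []
    for i in range(n):
        num = den = 0.0
        for k in range(n):
            for l in range(n):
                if k == i or l == i or k == l:
                    continue
                num += W[i, k] * W[i, l] * W[k, l]
                den += W[i, k] * W[i, l]
        cis.append(num / den if den > 0 else 0.0)
    return float(np.mean(cis))


def floyd_warshall_path_length(W):
    """Independent oracle: Floyd-Warshall on edge lengths 1/w."""
    n = W.shape[0]
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    for i in range(n):
        for j in range(n):
            if i != j and W[i, j] > 0:
                D[i, j] = 1.0 / W[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if D[i, k] + D[k, j] < D[i, j]:
                    D[i, j] = D[i, k] + D[k, j]
    off = D[~np.eye(n, dtype=bool)]
    return float(off.mean())


def uniform_complete(n, w=0.4):
    W = np.full((n, n), w)
    np.fill_diagonal(W, 0.0)
    return W


class TestClustering:
    def test_uniform_complete_reduces_to_weight(self):
        assert weighted_clustering(uniform_complete(7, 0.4)) == pytest.approx(
            0.4, abs=1e-12)

    def test_star_graph_is_zero(self):
        W = np.zeros((6, 6))
        W[0, 1:] = W[1:, 0] = 0.8
        assert weighted_clustering(W) == 0.0

    def test_matches_brute_force(self, rng, random_weights):
        for _ in range(25):
            W = random_weights(8, rng)
            assert weighted_clustering(W) == pytest.approx(
                brute_force_clustering(W), abs=1e-12)

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            weighted_clustering(np.zeros((2, 2)))


class TestPathLength:
    def test_uniform_complete_closed_form(self):
        assert weighted_path_length(uniform_complete(7, 0.4)) == \
            pytest.approx(2.5, abs=1e-12)

    def test_indirect_route_shorter(self):
        W = np.array([[0.0, 0.5, 0.1],
                      [0.5, 0.0, 0.5],
                      [0.1, 0.5, 0.0]])
        assert weighted_path_length(W) == pytest.approx((2 + 2 + 4) / 3,
                                                        abs=1e-12)

    def test_matches_floyd_warshall(self, rng, random_weights):
        for _ in range(25):
            W = random_weights(8, rng)
            assert weighted_path_length(W) == pytest.approx(
                floyd_warshall_path_length(W), abs=1e-12)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="no network"):
            weighted_path_length(np.zeros((4, 4)))

    def test_disconnected_warns_and_stays_finite(self):
        W = np.zeros((4, 4))
        W[0, 1] = W[1, 0] = 0.5
        W[2, 3] = W[3, 2] = 0.25
        with pytest.warns(UserWarning, match="disconnected"):
            lw = weighted_path_length(W)
        assert np.isfinite(lw)


class TestSurrogates:
    def test_weight_multiset_preserved(self, rng, random_weights):
        W = random_weights(10, rng)
        S = shuffle_surrogate(W, rng)
        iu = np.triu_indices(10, 1)
        np.testing.assert_allclose(np.sort(W[iu]), np.sort(S[iu]))
        np.testing.assert_allclose(S, S.T)
        assert np.all(np.diag(S) == 0)

    def test_uniform_graph_fixed_point(self, rng):
        W = uniform_complete(6, 0.3)
        np.testing.assert_array_equal(shuffle_surrogate(W, rng), W)

    def test_seed_reproducibility(self, random_weights):
        W = random_weights(10, np.random.default_rng(4))
        a = shuffle_surrogate(W, np.random.default_rng(7))
        b = shuffle_surrogate(W, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)


class TestNormalizedMeasures:
    def test_uniform_complete_exactly_one(self):
        m = normalized_measures(uniform_complete(8, 0.4), n_surrogates=10,
                                seed=0)
        assert m.gamma == pytest.approx(1.0, abs=1e-12)
        assert m.lambda_ == pytest.approx(1.0, abs=1e-12)

    def test_iid_network_self_normalizes(self, rng, random_weights):
        gs, ls = [], []
        for k in range(30):
            W = random_weights(19, rng)
            m = normalized_measures(W, n_surrogates=20, seed=k)
            gs.append(m.gamma)
            ls.append(m.lambda_)
        for vals in (gs, ls):
            se = np.std(vals, ddof=1) / np.sqrt(len(vals))
            assert abs(np.mean(vals) - 1.0) < 3 * se + 1e-3

    def test_ring_lattice_is_ordered_regime(self):
        n, k = 19, 4
        W = np.full((n, n), 0.05)
        np.fill_diagonal(W, 0.0)
        for i in range(n):
            for d in (1, 2):
                W[i, (i + d) % n] = W[(i + d) % n, i] = 0.6
        m = normalized_measures(W, n_surrogates=50, seed=3)
        assert m.gamma > 1.0
        assert m.lambda_ > 1.0

    def test_scale_invariance(self, rng, random_weights):
        W = random_weights(12, rng)
        a = normalized_measures(W, n_surrogates=10, seed=5)
        b = normalized_measures(0.37 * W, n_surrogates=10, seed=5)
        assert b.gamma == pytest.approx(a.gamma, rel=1e-12)
        assert b.lambda_ == pytest.approx(a.lambda_, rel=1e-12)

    def test_degradation_monotone_under_partial_shuffle(self, rng):
        """Partially shuffling an ordered lattice walks gamma/lambda toward 1."""
        n, k = 19, 4
        W0 = np.full((n, n), 0.05)
        np.fill_diagonal(W0, 0.0)
        for i in range(n):
            for d in (1, 2):
                W0[i, (i + d) % n] = W0[(i + d) % n, i] = 0.6
        iu = np.triu_indices(n, 1)

        def partial_shuffle(W, f, r):
            vals = W[iu].copy()
            m = int(round(f * len(vals)))
            idx = r.choice(len(vals), size=m, replace=False)
            sub = vals[idx].copy()
            r.shuffle(sub)
            vals[idx] = sub
            S = np.zeros_like(W)
            S[iu] = vals
            return S + S.T

        means_g, means_l = [], []
        for f in (0.0, 0.25, 0.5, 1.0):
            gs, ls = [], []
            for rep in range(12):
                r = np.random.default_rng(1000 * rep + int(f * 100))
                m = normalized_measures(partial_shuffle(W0, f, r),
                                        n_surrogates=20, seed=rep)
                gs.append(m.gamma)
                ls.append(m.lambda_)
            means_g.append(np.mean(gs))
            means_l.append(np.mean(ls))
        slack = 0.02
        assert all(b <= a + slack for a, b in zip(means_g, means_g[1:]))
        assert all(b <= a + slack for a, b in zip(means_l, means_l[1:]))


class TestPerRecordingAggregation:
    def _mat(self, W, band="beta", epoch_id=0):
        return ConnectivityMatrix(weights=W, labels=[f"c{i}" for i in
                                                     range(W.shape[0])],
                                  band=band, epoch_id=epoch_id)

    def test_identical_epochs_match_single(self, rng, random_weights):
        W = random_weights(8, rng, low=0.1, high=0.9)
        W = np.clip(W, 0, 1)
        mats = [self._mat(W, epoch_id=k) for k in range(4)]
        both = measures_per_recording(mats, n_surrogates=10, seed=9)
        one = measures_per_recording(mats[:1], n_surrogates=10, seed=9)
        assert both.cw == pytest.approx(one.cw)
        assert both.lw == pytest.approx(one.lw)

    def test_matrix_averaging_order_option(self, rng, random_weights):
        mats = [self._mat(np.clip(random_weights(8, rng), 0, 1), epoch_id=k)
                for k in range(3)]
        a = measures_per_recording(mats, n_surrogates=10, seed=1,
                                   average="measures")
        b = measures_per_recording(mats, n_surrogates=10, seed=1,
                                   average="matrix")
        assert a.per_epoch is not None and len(a.per_epoch) == 3
        assert b.per_epoch is None
        assert a.cw != b.cw  # genuinely different aggregation orders

    def test_mixed_bands_rejected(self, rng, random_weights):
        W = np.clip(random_weights(5, rng), 0, 1)
        mats = [self._mat(W, band="alpha"), self._mat(W, band="beta")]
        with pytest.raises(ValueError, match="mixed bands"):
            measures_per_recording(mats)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            measures_per_recording([])


def test_estimator_interface(rng, random_weights):
    W = np.clip(random_weights(10, rng), 0, 1)
    est = SmallWorldMetrics(n_surrogates=10, seed=2).fit(W)
    assert est.gamma_ == est.measures_.gamma
    assert est.get_params()["n_surrogates"] == 10
    est2 = SmallWorldMetrics(n_surrogates=10, seed=2).fit(W)
    assert est.gamma_ == est2.gamma_  # deterministic under fixed seed
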