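import math
from dataclasses import replace

import numpy as np
import pytest

from tspminimax import (
    MinimaxConfig,
    bandwidth_from_query,
    confidence_interval,
    estimate,
    fit_at_query,
    gaussian_kernel,
    is_confidently_predictable,
    kernel_matrix,
    m_bound,
    predict_from_fit,
    sigma_sweep,
    suggested_sigma_lower_limit,
    tikhonov_fit,
    tikhonov_fit_direct,
)
from tspminimax.local_minimax import MinimaxError


class TestKernel:
    def test_zero_distance(self):
        assert gaussian_kernel([1.0, 2.0], [1.0, 2.0], 0.7) == 1.0

    def test_analytic_value(self):
        # distance sigma*sqrt(2) -> exp(-1)
        sigma = 1.3
        u = np.zeros(3)
        v = np.array([sigma * math.sqrt(2.0), 0.0, 0.0])
        assert gaussian_kernel(u, v, sigma) == pytest.approx(math.exp(-1.0), rel=1e-12)

    def test_kernel_matrix_spd(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(5, 4))
        K = kernel_matrix(X, X, 0.9)
        np.testing.assert_allclose(K, K.T, atol=1e-15)
        assert np.linalg.eigvalsh(K).min() > 0

    def test_bad_sigma(self):
        with pytest.raises(MinimaxError):
            gaussian_kernel([0.0], [1.0], 0.0)


class TestBandwidth:
    def test_half_fraction(self):
        train = np.array([[0.0], [2.0]])
        assert bandwidth_from_query([0.0], train, 0.5) == 1.0

    def test_point7_fraction(self):
        train = np.array([[10.0, 0.0], [3.0, 0.0]])
        assert bandwidth_from_query([0.0, 0.0], train, 0.7) == pytest.approx(7.0)

    def test_single_point(self):
        assert bandwidth_from_query([0.0], [[3.0]], 0.5) == 1.5

    def test_degenerate_geometry(self):
        with pytest.raises(MinimaxError, match="bandwidth"):
            bandwidth_from_query([1.0], [[1.0], [1.0]], 0.5)


class TestMBound:
    def test_zero_radius(self):
        assert m_bound(0.0, 1.0, 0.5) == pytest.approx(math.sqrt(0.5), rel=1e-12)

    def test_closed_form(self):
        sigma = 1.0
        r = sigma * math.sqrt(2.0)
        assert m_bound(r, sigma, 0.5) == pytest.approx(
            math.sqrt(0.5) * math.exp(0.5), rel=1e-12
        )

    def test_monotone_in_radius(self):
        radii = np.linspace(0.0, 3.0, 20)
        vals = [m_bound(r, 1.1, 0.4) for r in radii]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_max_min_kernel_grid_search(self):
        # verify c = max_x min_y K(y, x) = exp(-r^2 / (2 sigma^2)) on a 2-D
        # ball by brute sampling (min is attained on the boundary, max at
        # the center)
        rng = np.random.default_rng(1)
        sigma, r = 0.8, 1.1
        theta = np.linspace(0.0, 2.0 * np.pi, 400, endpoint=False)
        boundary = r * np.stack([np.cos(theta), np.sin(theta)], axis=1)
        interior = rng.normal(size=(3000, 2))
        interior = interior[np.linalg.norm(interior, axis=1) <= 1.0] * r
        xs = np.vstack([np.zeros((1, 2)), boundary, interior])
        ys = np.vstack([boundary, interior, np.zeros((1, 2))])
        K = kernel_matrix(ys, xs, sigma)
        c_grid = K.min(axis=0).max()
        c_closed = math.exp(-(r**2) / (2.0 * sigma**2))
        assert c_grid == pytest.approx(c_closed, rel=2e-2)
        assert m_bound(r, sigma, 0.5) == pytest.approx(
            math.sqrt(0.5) / math.sqrt(c_closed), rel=1e-12
        )

    def test_negative_radius(self):
        with pytest.raises(MinimaxError):
            m_bound(-0.1, 1.0, 0.5)


class TestTikhonovFit:
    def test_hand_example_single_neighbor(self):
        # i=1, neighbor at distance 1, sigma=1, alpha=0.5
        M2 = 0.5 * math.exp(0.5)
        w, L = tikhonov_fit(np.zeros(1), np.array([[1.0]]), 1.0, math.sqrt(M2))
        kv = math.exp(-0.5)
        gamma = 0.25 / M2
        assert w[0] == pytest.approx(kv / (1.0 + gamma), rel=1e-12)
        assert w[0] == pytest.approx(0.465397, abs=5e-6)
        assert L == pytest.approx(M2 * (1.0 - kv * w[0]), rel=1e-12)
        assert L == pytest.approx(0.591663, abs=5e-6)

    def test_paths_agree(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            k = rng.integers(1, 11)
            i = rng.integers(1, 26)
            q = rng.normal(size=k)
            X = rng.normal(size=(i, k))
            sigma = float(rng.uniform(0.5, 2.0))
            M = float(rng.uniform(0.72, 3.0))
            w1, L1 = tikhonov_fit(q, X, sigma, M)
            w2, L2 = tikhonov_fit_direct(q, X, sigma, M)
            np.testing.assert_allclose(w1, w2, atol=1e-10)
            assert L1 == pytest.approx(L2, abs=1e-10)

    def test_bound_range(self):
        rng = np.random.default_rng(3)
        for M in (0.8, 2.0, 50.0, 1e4):
            q = rng.normal(size=4)
            X = rng.normal(size=(6, 4))
            _, L = tikhonov_fit(q, X, 1.0, M)
            assert 0.0 <= L <= M**2

    def test_duplicate_neighbors_rejected(self):
        X = np.array([[1.0, 0.0], [1.0, 0.0]])
        with pytest.raises(MinimaxError, match="dedup"):
            tikhonov_fit(np.zeros(2), X, 1.0, 1.0)


class TestEstimate:
    def _instance(self, seed=0, n=12, k=3):
        rng = np.random.default_rng(seed)
        train = rng.normal(size=(n, k))
        labels = rng.integers(0, 2, size=n)
        labels[:2] = [0, 1]
        query = rng.normal(size=k)
        return query, train, labels

    def test_zero_adjustment_identity(self):
        query, train, labels = self._instance()
        pred = estimate(query, train, labels, MinimaxConfig(adjustment_e=0.0))
        assert pred.f_adjusted == pred.f_raw

    def test_all_labels_one(self):
        query, train, _ = self._instance()
        labels = np.ones(train.shape[0], dtype=int)
        cfg = MinimaxConfig(alpha=0.5)
        pred = estimate(query, train, labels, cfg)
        wsum = pred.fit.weights.sum()
        # F = alpha + (1 - alpha) * sum(w)
        assert pred.f_raw == pytest.approx(0.5 + 0.5 * wsum, abs=1e-12)
        if wsum >= 0:
            assert pred.class_call == 1

    def test_composes_suboperations(self):
        query, train, labels = self._instance(seed=5, n=8)
        cfg = MinimaxConfig()
        sigma = bandwidth_from_query(query, train, cfg.sigma_fraction)
        d = np.linalg.norm(train - query, axis=1)
        order = np.argsort(d, kind="stable")
        best = None
        for i in range(1, len(order) + 1):
            nbrs = train[order[:i]]
            M = m_bound(float(d[order[i - 1]]), sigma, cfg.alpha)
            w, L = tikhonov_fit(query, nbrs, sigma, M)
            if best is None or L < best[0]:
                best = (L, i, w)
        L, i_star, w = best
        w_star = cfg.alpha * (1.0 - w.sum())
        f_manual = w_star + w @ labels[order[:i_star]]
        pred = estimate(query, train, labels, cfg)
        assert pred.fit.i == i_star
        assert pred.f_raw == pytest.approx(f_manual, abs=1e-12)
        assert pred.rmse_bound == pytest.approx(math.sqrt(L), abs=1e-12)

    def test_w_star_identity(self):
        for seed in range(5):
            query, train, labels = self._instance(seed=seed)
            pred = estimate(query, train, labels, MinimaxConfig(alpha=0.3))
            assert pred.fit.w_star == pytest.approx(
                0.3 * (1.0 - pred.fit.weights.sum()), abs=1e-15
            )

    def test_half_adjustment_label_free(self):
        query, train, labels = self._instance(seed=9)
        cfg = MinimaxConfig(adjustment_e=0.5)
        pred = estimate(query, train, labels, cfg)
        rng = np.random.default_rng(1)
        pred2 = estimate(query, train, rng.permutation(labels), cfg)
        # with e = 0.5 every label is replaced by 0.5
        expected = pred.fit.w_star + 0.5 * pred.fit.weights.sum()
        assert pred.f_adjusted == pytest.approx(expected, abs=1e-12)
        assert pred2.f_adjusted == pytest.approx(expected, abs=1e-12)

    def test_label_permutation_leaves_uncertainty(self):
        query, train, labels = self._instance(seed=2, n=15)
        cfg = MinimaxConfig()
        rng = np.random.default_rng(0)
        base = estimate(query, train, labels, cfg)
        for _ in range(5):
            perm = estimate(query, train, rng.permutation(labels), cfg)
            assert perm.fit.i == base.fit.i
            assert perm.rmse_bound == base.rmse_bound
            np.testing.assert_array_equal(perm.fit.weights, base.fit.weights)

    def test_training_order_permutation_invariant(self):
        query, train, labels = self._instance(seed=7, n=20)
        cfg = MinimaxConfig()
        base = estimate(query, train, labels, cfg)
        rng = np.random.default_rng(3)
        perm = rng.permutation(train.shape[0])
        other = estimate(query, train[perm], labels[perm], cfg)
        assert other.fit.i == base.fit.i
        assert other.f_raw == pytest.approx(base.f_raw, abs=1e-12)
        assert other.rmse_bound == pytest.approx(base.rmse_bound, abs=1e-12)
        assert other.ci_low == pytest.approx(base.ci_low, abs=1e-12)
        assert other.class_call == base.class_call
        assert other.cp_flag == base.cp_flag

    def test_bad_labels_rejected(self):
        query, train, labels = self._instance()
        labels = labels.astype(float)
        labels[0] = 0.5
        with pytest.raises(MinimaxError, match="labels"):
            estimate(query, train, labels, MinimaxConfig())


class TestConfidenceInterval:
    def test_patient_244_lower_endpoint(self):
        low, _ = confidence_interval(0.579, 0.072, 0.10)
        assert round(low, 3) == 0.462

    def test_patient_253_lower_endpoint(self):
        low, _ = confidence_interval(0.837, 0.159, 0.10)
        assert round(low, 3) == 0.579

    def test_patient_12_lower_endpoint_exact_quantile(self):
        # exact quantiles give 0.830; the rounded 1.62 multiplier gives 0.831
        low, _ = confidence_interval(0.962, 0.081, 0.10)
        assert round(low, 3) == 0.830

    def test_zero_rho(self):
        assert confidence_interval(0.4, 0.0, 0.10) == (0.4, 0.4)

    def test_negative_unclipped_estimate(self):
        # estimate below zero: reported interval still valid and ordered
        low, high = confidence_interval(-0.1137, 0.209, 0.10)
        assert low == 0.0
        assert high == pytest.approx(0.226, abs=5e-4)

    def test_negative_rho_rejected(self):
        with pytest.raises(MinimaxError):
            confidence_interval(0.5, -0.01, 0.10)


class TestConfidentPredictability:
    @pytest.mark.parametrize(
        "ci,expected",
        [
            ((0.831, 1.0), True),
            ((0.0, 0.226), True),
            ((0.462, 1.0), False),
            ((0.579, 1.0), False),
        ],
    )
    def test_narrative_cases(self, ci, expected):
        assert is_confidently_predictable(ci, 0.35) is expected

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            low = rng.uniform(0.0, 1.0)
            high = rng.uniform(low, 1.0)
            p = rng.uniform(0.01, 0.5)
            p2 = rng.uniform(p, 0.5)
            if is_confidently_predictable((low, high), p):
                assert is_confidently_predictable((low, high), p2)

    def test_invalid_interval(self):
        with pytest.raises(MinimaxError):
            is_confidently_predictable((0.5, 0.4), 0.35)


class TestSigmaSweep:
    def _instance(self):
        rng = np.random.default_rng(8)
        train = rng.normal(size=(10, 4))
        labels = rng.integers(0, 2, size=10)
        labels[:2] = [0, 1]
        return rng.normal(size=4), train, labels

    def test_default_grid_length(self):
        query, train, labels = self._instance()
        sweep = sigma_sweep(query, train, labels, MinimaxConfig())
        assert len(sweep.fractions) == 13
        assert len(sweep.predictions) == 13
        assert sweep.fractions[0] == pytest.approx(0.2)
        assert sweep.fractions[-1] == pytest.approx(1.4)

    def test_ci_brackets_estimate(self):
        query, train, labels = self._instance()
        sweep = sigma_sweep(query, train, labels, MinimaxConfig())
        for pred in sweep.predictions:
            assert 0.0 <= pred.ci_low <= pred.f_reported <= pred.ci_high <= 1.0

    def test_lower_limit_uses_second_closest_of_ten(self):
        query, train, labels = self._instance()
        d = np.sort(np.linalg.norm(train - query, axis=1))
        expected = d[1] / d[-1]  # ceil(10 / 5) = 2nd closest
        assert suggested_sigma_lower_limit(query, train) == pytest.approx(expected)
        assert sigma_sweep(query, train, labels, MinimaxConfig()).suggested_lower_limit == pytest.approx(expected)

    def test_empty_grid_rejected(self):
        query, train, labels = self._instance()
        with pytest.raises(MinimaxError, match="grid"):
            sigma_sweep(query, train, labels, MinimaxConfig(), fractions=[])


class TestConfig:
    def test_valid_defaults(self):
        cfg = MinimaxConfig()
        assert cfg.sigma_fraction == 0.5 and cfg.alpha == 0.5
        assert cfg.beta == 0.10 and cfg.p_threshold == 0.35
        assert cfg.adjustment_e == 0.0 and cfg.k == 10

    def test_exact_quantile_multiplier(self):
        cfg = MinimaxConfig(beta=0.10)
        assert cfg.z_beta == pytest.approx(1.281552, abs=1e-6)
        assert cfg.ci_multiplier == pytest.approx(1.6255382, abs=1e-6)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"sigma_fraction": 0.0},
            {"alpha": 1.0},
            {"beta": 0.6},
            {"p_threshold": 0.0},
            {"adjustment_e": 0.6},
            {"k": 0},
        ],
    )
    def test_invalid_config(self, kwargs):
        with pytest.raises(MinimaxError):
            MinimaxConfig(**kwargs)
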