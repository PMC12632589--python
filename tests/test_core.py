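import math

import numpy as np
import pytest
from scipy import stats

from ppsi import (
    Assignment,
    DataMatrix,
    FitConfig,
    GaussianConstants,
    assign,
    build_basis,
    dataset_loglik,
    evaluate_progression,
    fit,
    log_pdf,
    observation_loglik,
    predict,
    total_loss,
)

STD_NORMAL_PEAK = -0.5 * math.log(2 * math.pi)  # ~= -0.9189385


class TestBasis:
    def test_linear_column(self):
        basis = build_basis(K=2, D=1)
        np.testing.assert_allclose(basis.matrix[:, 0], [0.0, 0.5, 1.0])

    def test_quadratic_rows(self):
        basis = build_basis(K=2, D=2)
        np.testing.assert_allclose(basis.matrix, [[0, 0], [0.5, 0.25], [1, 1]])

    @pytest.mark.parametrize("K,D", [(1, 1), (5, 3), (20, 4), (15, 2)])
    def test_boundary_and_monotonicity(self, K, D):
        m = build_basis(K, D).matrix
        assert np.all(m[0] == 0) and np.all(m[-1] == 1)
        assert np.all(np.diff(m, axis=0) > 0)  # strictly increasing in k per column
        assert m.min() >= 0 and m.max() <= 1

    @pytest.mark.parametrize("K,D", [(0, 1), (1, 0), (-2, 2)])
    def test_rejects_nonpositive(self, K, D):
        with pytest.raises(ValueError):
            build_basis(K, D)


class TestEvaluate:
    def test_zero_map(self):
        basis = build_basis(4, 2)
        M = evaluate_progression(np.zeros((2, 3, 2)), basis)
        assert M.shape == (5, 3, 2)
        assert np.all(M == 0)

    def test_cancellation_at_endpoint(self):
        # theta = (1, -1) for a single quadratic feature: t - t^2 vanishes at t=1
        basis = build_basis(4, 2)
        theta = np.array([[[1.0]], [[-1.0]]])
        M = evaluate_progression(theta, basis)
        assert M[-1, 0, 0] == pytest.approx(0.0)

    def test_matches_scalar_polynomial_loop(self):
        rng = np.random.default_rng(3)
        K, D, P, S = 5, 3, 4, 2
        theta = rng.normal(size=(D, P, S))
        M = evaluate_progression(theta, build_basis(K, D))
        for k in range(K + 1):
            t = k / K
            for p in range(P):
                for s in range(S):
                    expected = sum(theta[d, p, s] * t ** (d + 1) for d in range(D))
                    assert M[k, p, s] == pytest.approx(expected, abs=1e-12)

    def test_zero_intercept_row(self):
        rng = np.random.default_rng(1)
        M = evaluate_progression(rng.normal(size=(3, 6, 4)), build_basis(8, 3))
        assert np.all(M[0] == 0)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            evaluate_progression(np.zeros((3, 2, 1)), build_basis(4, 2))


class TestLogPdf:
    def test_standard_normal_peak(self):
        c = GaussianConstants.from_sigma(1.0)
        assert log_pdf(0.0, 0.0, c) == pytest.approx(STD_NORMAL_PEAK, abs=1e-7)
        assert log_pdf(0.0, 1.0, c) == pytest.approx(STD_NORMAL_PEAK - 0.5, abs=1e-7)

    def test_matches_direct_normal_logpdf(self):
        rng = np.random.default_rng(42)
        mu = rng.normal(scale=3, size=1000)
        x = rng.normal(scale=3, size=1000)
        sigma = rng.uniform(0.1, 5.0, size=1000)
        for m, xx, s in zip(mu, x, sigma):
            c = GaussianConstants.from_sigma(s)
            assert log_pdf(m, xx, c) == pytest.approx(
                stats.norm.logpdf(xx, loc=m, scale=s), abs=1e-10
            )

    def test_constants_consistency(self):
        c = GaussianConstants.from_sigma(2.7)
        assert c.alpha * math.sqrt(math.pi * c.beta) == pytest.approx(1.0, abs=1e-12)


class TestObservationLoglik:
    def test_all_centroids_at_zero(self):
        M = evaluate_progression(np.zeros((1, 1, 2)), build_basis(3, 1))
        phi = observation_loglik([0.0], M, GaussianConstants.from_sigma(1.0))
        assert phi.shape == (2, 4)
        np.testing.assert_allclose(phi, STD_NORMAL_PEAK, atol=1e-7)

    def test_matches_product_domain(self):
        rng = np.random.default_rng(5)
        theta = rng.normal(size=(2, 2, 2))
        basis = build_basis(4, 2)
        M = evaluate_progression(theta, basis)
        c = GaussianConstants.from_sigma(1.0)
        x = rng.normal(size=2)
        phi = observation_loglik(x, M, c)
        for s in range(2):
            for k in range(5):
                product = np.prod(stats.norm.pdf(x, loc=M[k, :, s], scale=1.0))
                assert math.exp(phi[s, k]) == pytest.approx(product, rel=1e-8)

    def test_translation_invariance(self):
        rng = np.random.default_rng(8)
        theta = rng.normal(size=(2, 3, 2))
        basis = build_basis(5, 2)
        M = evaluate_progression(theta, basis)
        c = GaussianConstants.from_sigma(1.0)
        x = rng.normal(size=3)
        phi = observation_loglik(x, M, c)
        # shift one feature and its centroid row by the same constant
        M2 = M.copy()
        M2[:, 1, :] += 3.7
        x2 = x.copy()
        x2[1] += 3.7
        np.testing.assert_allclose(observation_loglik(x2, M2, c), phi, atol=1e-9)

    def test_length_mismatch(self):
        M = evaluate_progression(np.zeros((1, 2, 1)), build_basis(3, 1))
        with pytest.raises(ValueError):
            observation_loglik([0.0], M, GaussianConstants.from_sigma(1.0))


class TestAssign:
    def test_unique_maximum(self):
        phi = np.full((3, 10), -5.0)
        phi[1, 7] = -1.0
        a = assign(phi)
        assert (a.subtype, a.stage) == (2, 7)
        assert a.loglik == -1.0

    def test_tie_break_constant(self):
        a = assign(np.zeros((3, 5)))
        assert (a.subtype, a.stage) == (1, 0)

    def test_tie_break_stage_before_subtype(self):
        phi = np.full((2, 4), -9.0)
        phi[1, 1] = 0.0  # subtype 2, stage 1
        phi[0, 2] = 0.0  # subtype 1, stage 2 -- later stage loses
        a = assign(phi)
        assert (a.subtype, a.stage) == (2, 1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_scan(self, seed):
        phi = np.random.default_rng(seed).normal(size=(4, 9))
        a = assign(phi)
        best = max(
            ((phi[s, k], s, k) for s in range(4) for k in range(9)),
            key=lambda c: (c[0], -c[2], -c[1]),
        )
        assert (a.subtype - 1, a.stage) == (best[1], best[2])
        assert a.loglik == pytest.approx(phi.max())


class TestTotalLoss:
    def test_single_zero_record(self):
        data = DataMatrix(X=np.zeros((1, 1)), feature_names=["f"], zscored=True)
        loss = total_loss(
            data, np.zeros((1, 1, 1)), build_basis(3, 1), GaussianConstants.from_sigma(1.0), 0.0
        )
        assert loss == pytest.approx(-STD_NORMAL_PEAK, abs=1e-7)

    def test_linear_in_penalty(self):
        rng = np.random.default_rng(2)
        data = DataMatrix(X=rng.normal(size=(5, 3)), feature_names=list("abc"), zscored=True)
        theta = rng.normal(size=(2, 3, 2))
        basis = build_basis(4, 2)
        c = GaussianConstants.from_sigma(1.0)
        l0 = total_loss(data, theta, basis, c, 0.1)
        l1 = total_loss(data, theta, basis, c, 0.35)
        assert l1 - l0 == pytest.approx(0.25 * np.abs(theta).sum(), rel=1e-10)

    def test_matches_naive_assembly(self):
        rng = np.random.default_rng(9)
        data = DataMatrix(X=rng.normal(size=(6, 2)), feature_names=["u", "v"], zscored=True)
        theta = rng.normal(size=(2, 2, 3))
        basis = build_basis(5, 2)
        c = GaussianConstants.from_sigma(1.3)
        M = evaluate_progression(theta, basis)
        expected = 0.0
        for n in range(6):
            phi = np.array(
                [
                    [
                        sum(log_pdf(M[k, p, s], data.X[n, p], c) for p in range(2))
                        for k in range(6)
                    ]
                    for s in range(3)
                ]
            )
            expected -= phi.max()
        expected += 0.07 * np.abs(theta).sum()
        assert total_loss(data, theta, basis, c, 0.07) == pytest.approx(expected, rel=1e-10)

    def test_log_product_domain_equivalence(self):
        # exp of the log-domain dataset likelihood equals the product-domain value
        rng = np.random.default_rng(4)
        data = DataMatrix(X=rng.normal(size=(4, 2)), feature_names=["u", "v"], zscored=True)
        theta = rng.normal(scale=0.5, size=(1, 2, 2))
        basis = build_basis(3, 1)
        c = GaussianConstants.from_sigma(1.0)
        M = evaluate_progression(theta, basis)
        loglik = dataset_loglik(data.X, theta, basis, c)
        product = 1.0
        for n in range(4):
            cells = [
                np.prod(stats.norm.pdf(data.X[n], loc=M[k, :, s], scale=1.0))
                for s in range(2)
                for k in range(4)
            ]
            product *= max(cells)
        assert math.exp(loglik) == pytest.approx(product, rel=1e-8)


class TestFit:
    def test_seeded_determinism(self, tiny_data):
        cfg = FitConfig(D=1, S=2, K=4, iterations=50, seed=123)
        m1 = fit(tiny_data, cfg)
        m2 = fit(tiny_data, cfg)
        assert np.array_equal(m1.theta, m2.theta)
        assert m1.loss_history == m2.loss_history

    def test_full_batch_loss_decreases(self, tiny_data):
        cfg = FitConfig(
            D=1, S=1, K=4, iterations=300, minibatch_fraction=1.0, l1_penalty=0.0, seed=0
        )
        m = fit(tiny_data, cfg)
        assert len(m.loss_history) == 300
        assert m.loss_history[-1] <= m.loss_history[0]

    def test_recovers_noiseless_single_subtype(self):
        # records placed exactly at the stage centroids of a known model
        rng = np.random.default_rng(6)
        K, D, P = 10, 2, 5
        theta_true = rng.normal(scale=1.5, size=(D, P, 1))
        basis = build_basis(K, D)
        M = evaluate_progression(theta_true, basis)
        stages = np.tile(np.arange(K + 1), 6)
        X = M[stages, :, 0]
        data = DataMatrix(X=X, feature_names=[f"f{p}" for p in range(P)], zscored=True)
        model = fit(
            data,
            FitConfig(D=D, S=1, K=K, iterations=3000, minibatch_fraction=1.0,
                      l1_penalty=0.0, seed=1),
        )
        assert np.abs(model.theta - theta_true).max() < 0.1
        assigned = [a.stage for a in predict(model, data)]
        r = np.corrcoef(stages, assigned)[0, 1]
        assert abs(r) >= 0.99

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            FitConfig(D=0, S=1)
        with pytest.raises(ValueError):
            FitConfig(D=1, S=1, minibatch_fraction=0.0)
        with pytest.raises(ValueError):
            FitConfig(D=1, S=1, sigma=-1.0)


class TestPredict:
    def test_centroid_record_assigned_exactly(self, fitted_model):
        M = fitted_model.evaluate()
        x = M[3, :, 0]  # the (subtype 1, stage 3) centroid
        data = DataMatrix(
            X=x[None, :], feature_names=list(fitted_model.feature_names), zscored=True
        )
        a = predict(fitted_model, data)[0]
        assert (a.subtype, a.stage) == (1, 3)

    def test_permutation_equivariance(self, fitted_model, easy_dataset):
        data, _ = easy_dataset
        perm = np.random.default_rng(0).permutation(data.n_records)
        permuted = DataMatrix(
            X=data.X[perm],
            feature_names=list(data.feature_names),
            record_ids=[data.record_ids[i] for i in perm],
            zscored=True,
        )
        base = predict(fitted_model, data)
        shuffled = predict(fitted_model, permuted)
        for i, j in enumerate(perm):
            assert shuffled[i] == base[j]

    def test_duplicating_a_record_changes_nothing(self, fitted_model, easy_dataset):
        data, _ = easy_dataset
        dup = DataMatrix(
            X=np.vstack([data.X, data.X[:1]]),
            feature_names=list(data.feature_names),
            zscored=True,
        )
        base = predict(fitted_model, data)
        extended = predict(fitted_model, dup)
        assert extended[:-1] == base
        assert extended[-1] == base[0]

    def test_feature_mismatch_lists_names(self, fitted_model):
        data = DataMatrix(X=np.zeros((1, 2)), feature_names=["nope", "poly0"], zscored=True)
        with pytest.raises(ValueError, match="nope"):
            predict(fitted_model, data)


class TestDataMatrix:
    def test_rejects_missing(self):
        X = np.array([[1.0, np.nan]])
        with pytest.raises(ValueError, match="missing"):
            DataMatrix(X=X, feature_names=["a", "b"])

    def test_rejects_empty(self):
        with pytest.raises(ValueError):
            DataMatrix(X=np.empty((0, 2)), feature_names=["a", "b"])

    def test_unflagged_data_warns_at_fit(self, tiny_data):
        plain = DataMatrix(X=tiny_data.X, feature_names=tiny_data.feature_names)
        with pytest.warns(UserWarning, match="z-scor"):
            fit(plain, FitConfig(D=1, S=1, K=3, iterations=5))


def test_loss_evaluation_scales_linearly():
    """Runtime of one loss evaluation is O(SKPN): doubling any one of
    S, K, P, N at most triples the time."""
    import time

    def timed(n, p, s, k):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(n, p))
        theta = rng.normal(size=(2, p, s))
        basis = build_basis(k, 2)
        c = GaussianConstants.from_sigma(1.0)
        best = math.inf
        for _ in range(5):
            t0 = time.perf_counter()
            dataset_loglik(X, theta, basis, c)
            best = min(best, time.perf_counter() - t0)
        return best

    base = dict(n=4000, p=24, s=3, k=24)
    t_base = timed(**base)
    for dim in ("n", "p", "s", "k"):
        doubled = dict(base)
        doubled[dim] *= 2
        assert timed(**doubled) / t_base < 3.0, f"doubling {dim} exceeded linear scaling"
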