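"""PCA, BPNN, metrics, cross-validation and repeated-run statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ricefusion.chemometrics import (
    BPNNConfig,
    DegenerateDataError,
    MetricPair,
    backprop_gradients,
    bpnn_predict,
    bpnn_train,
    cross_validate,
    derive_seeds,
    fold_assignment,
    load_bpnn,
    pca_fit,
    pca_transform,
    pearson_r,
    repeat_runs,
    rmse,
    save_bpnn,
)


# ---------------------------------------------------------------------------
# PCA


class TestPCA:
    def test_collinear_points_have_rank_one_spectrum(self):
        t = np.linspace(0, 1, 20)
        X = np.column_stack([2 * t + 1, -3 * t + 4])
        model = pca_fit(X, 2)
        np.testing.assert_allclose(
            model.explained_variance_ratio, [1.0, 0.0], atol=1e-9
        )

    def test_matches_covariance_eigendecomposition(self):
        """Independent oracle: eigh on the sample covariance matrix."""
        rng = np.random.default_rng(0)
        for n, p in [(5, 3), (10, 8), (8, 4)]:
            X = rng.normal(size=(n, p))
            k = min(n - 1, p)
            model = pca_fit(X, k)
            cov = np.cov(X, rowvar=False, ddof=1)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1]
            evals, evecs = evals[order], evecs[:, order]
            np.testing.assert_allclose(
                model.explained_variance_ratio,
                (evals / evals.sum())[:k],
                atol=1e-8,
            )
            # loadings agree up to sign
            dots = np.abs(np.sum(model.loadings * evecs[:, :k], axis=0))
            np.testing.assert_allclose(dots, 1.0, atol=1e-8)

    def test_matches_sklearn(self):
        sklearn_pca = pytest.importorskip("sklearn.decomposition")
        rng = np.random.default_rng(1)
        X = rng.normal(size=(9, 6))
        model = pca_fit(X, 4)
        ref = sklearn_pca.PCA(n_components=4).fit(X)
        np.testing.assert_allclose(
            model.explained_variance_ratio,
            ref.explained_variance_ratio_,
            atol=1e-10,
        )
        dots = np.abs(np.sum(model.loadings * ref.components_.T, axis=0))
        np.testing.assert_allclose(dots, 1.0, atol=1e-10)

    def test_full_rank_reconstruction(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(12, 5))
        model = pca_fit(X, 5)
        scores = pca_transform(model, X)
        back = scores @ model.loadings.T
        np.testing.assert_allclose(back, X - model.mean, atol=1e-8)

    def test_training_scores_are_centred(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(30, 7))
        scores = pca_transform(pca_fit(X, 3), X)
        np.testing.assert_allclose(scores.mean(axis=0), 0, atol=1e-8)

    def test_mean_input_maps_to_zero_scores(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(10, 4))
        model = pca_fit(X, 2)
        np.testing.assert_allclose(
            pca_transform(model, model.mean), 0, atol=1e-10
        )

    def test_unit_loading_displacement_gives_unit_score(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(10, 4))
        model = pca_fit(X, 2)
        x = model.mean + model.loadings[:, 0]
        np.testing.assert_allclose(
            pca_transform(model, x), [1.0, 0.0], atol=1e-10
        )

    def test_transform_matches_matrix_product(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(15, 6))
        model = pca_fit(X, 4)
        Z = rng.normal(size=(7, 6))
        np.testing.assert_allclose(
            pca_transform(model, Z), (Z - model.mean) @ model.loadings
        )

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_orthonormal_loadings_and_monotone_cumulative_evr(self, seed):
        rng = np.random.default_rng(seed)
        n, p = int(rng.integers(4, 11)), int(rng.integers(2, 9))
        X = rng.normal(size=(n, p))
        k = min(n - 1, p)
        model = pca_fit(X, k)
        gram = model.loadings.T @ model.loadings
        np.testing.assert_allclose(gram, np.eye(k), atol=1e-8)
        evr = model.explained_variance_ratio
        assert (np.diff(evr) <= 1e-12).all()  # non-increasing
        cum = np.cumsum(evr)
        assert (np.diff(cum) >= -1e-12).all() and cum[-1] <= 1 + 1e-8
        assert cum[-1] == pytest.approx(1.0, abs=1e-8)  # complete basis

    def test_degenerate_and_invalid_inputs(self):
        with pytest.raises(DegenerateDataError):
            pca_fit(np.ones((5, 3)), 2)
        with pytest.raises(ValueError):
            pca_fit(np.random.default_rng(0).normal(size=(5, 3)), 5)
        model = pca_fit(np.random.default_rng(0).normal(size=(5, 3)), 2)
        with pytest.raises(ValueError, match="dimension"):
            pca_transform(model, np.zeros((2, 7)))


# ---------------------------------------------------------------------------
# BPNN


def _linear_data(n=30, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, 1, n)
    return x[:, None], 2 * x + 1


class TestBPNN:
    def test_zero_iterations_returns_untrained_but_reproducible_net(self):
        X, y = _linear_data()
        cfg = BPNNConfig(max_iterations=0, seed=42)
        m1, m2 = bpnn_train(cfg, X, y), bpnn_train(cfg, X, y)
        np.testing.assert_array_equal(
            bpnn_predict(m1, X), bpnn_predict(m2, X)
        )
        assert m1.n_epochs_run == 0

    def test_gradients_match_central_finite_differences(self):
        """Analytic backprop vs central differences on a 3-sample toy set."""
        rng = np.random.default_rng(7)
        X = rng.uniform(0, 1, size=(3, 2))
        y = rng.uniform(0, 1, size=3)
        weights = [rng.uniform(-0.5, 0.5, s) for s in [(2, 4), (4, 3), (3, 1)]]
        biases = [rng.uniform(-0.5, 0.5, (1, s)) for s in [4, 3, 1]]
        _, gWs, gbs = backprop_gradients(weights, biases, X, y)
        h = 1e-6
        for params, grads in [(weights, gWs), (biases, gbs)]:
            for P, G in zip(params, grads):
                for idx in np.ndindex(P.shape):
                    orig = P[idx]
                    P[idx] = orig + h
                    lp, _, _ = backprop_gradients(weights, biases, X, y)
                    P[idx] = orig - h
                    lm, _, _ = backprop_gradients(weights, biases, X, y)
                    P[idx] = orig
                    fd = (lp - lm) / (2 * h)
                    assert np.asarray(G).reshape(P.shape)[idx] == pytest.approx(
                        fd, rel=1e-5, abs=1e-8
                    )

    def test_training_reduces_rmse_on_linear_data(self):
        X, y = _linear_data()
        cfg = BPNNConfig(seed=3)
        untrained = bpnn_train(
            BPNNConfig(max_iterations=0, seed=3), X, y
        )
        trained = bpnn_train(cfg, X, y)
        assert rmse(y, bpnn_predict(trained, X)) < rmse(
            y, bpnn_predict(untrained, X)
        )

    def test_converged_linear_fit_predicts_within_5_percent(self):
        X, y = _linear_data()
        model = bpnn_train(BPNNConfig(seed=1), X, y)
        pred = bpnn_predict(model, X)
        assert np.abs(pred - y).max() < 0.05 * np.ptp(y)

    def test_duplicated_rows_get_identical_predictions(self):
        X, y = _linear_data()
        model = bpnn_train(BPNNConfig(seed=2), X, y)
        X2 = np.vstack([X[:5], X[:5]])
        pred = bpnn_predict(model, X2)
        np.testing.assert_array_equal(pred[:5], pred[5:])
        assert np.isfinite(pred).all()

    def test_infinite_target_runs_exactly_max_iterations(self):
        X, y = _linear_data()
        model = bpnn_train(
            BPNNConfig(max_iterations=17, target_rmse=np.inf, seed=0), X, y
        )
        assert model.n_epochs_run == 17

    def test_loose_target_stops_immediately(self):
        X, y = _linear_data()
        model = bpnn_train(
            BPNNConfig(max_iterations=100, target_rmse=10.0, seed=0), X, y
        )
        assert model.n_epochs_run == 1

    def test_three_hidden_layer_topology_selectable(self):
        X, y = _linear_data()
        model = bpnn_train(
            BPNNConfig(hidden_layers=(5, 5, 5), seed=0), X, y
        )
        assert [W.shape for W in model.weights] == [
            (1, 5), (5, 5), (5, 5), (5, 1)
        ]

    def test_degenerate_target_rejected(self):
        X, _ = _linear_data()
        with pytest.raises(DegenerateDataError):
            bpnn_train(BPNNConfig(), X, np.ones(len(X)))

    def test_dimension_mismatch_rejected(self):
        X, y = _linear_data()
        model = bpnn_train(BPNNConfig(seed=0), X, y)
        with pytest.raises(ValueError, match="dimension"):
            bpnn_predict(model, np.zeros((4, 3)))

    def test_save_load_round_trip(self, tmp_path):
        X, y = _linear_data()
        model = bpnn_train(BPNNConfig(seed=5), X, y)
        save_bpnn(model, tmp_path / "net.json")
        loaded = load_bpnn(tmp_path / "net.json")
        np.testing.assert_array_equal(
            bpnn_predict(model, X), bpnn_predict(loaded, X)
        )
        assert loaded.config == model.config


# ---------------------------------------------------------------------------
# metrics


class TestMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 5.0])
        assert pearson_r(y, y) == pytest.approx(1.0)
        assert rmse(y, y) == 0.0

    def test_hand_computed_rmse(self):
        assert rmse(np.array([1, 2, 3]), np.array([1, 2, 4])) == pytest.approx(
            np.sqrt(1 / 3)
        )

    def test_perfect_anticorrelation(self):
        y = np.array([1.0, 2.0, 3.0, 7.0])
        assert pearson_r(y, -y + 11) == pytest.approx(-1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DegenerateDataError):
            pearson_r(np.ones(5), np.arange(5.0))

    def test_metric_pair_validates_ranges(self):
        with pytest.raises(ValueError):
            MetricPair(r=1.5, rmse=0.1)
        with pytest.raises(ValueError):
            MetricPair(r=0.5, rmse=-0.1)


# ---------------------------------------------------------------------------
# cross-validation and repeated runs


class TestCrossValidate:
    def test_noiseless_linear_data_recovers_target(self):
        X, y = _linear_data(n=40, seed=1)
        result = cross_validate(BPNNConfig(seed=0), X, y, folds=5, seed=3)
        assert result.rmse < 0.05 * np.ptp(y)
        assert result.r > 0.99

    def test_leave_one_out_on_six_samples(self):
        X, y = _linear_data(n=6, seed=2)
        result = cross_validate(BPNNConfig(seed=0), X, y, folds=6, seed=0)
        assert np.isfinite(result.r) and np.isfinite(result.rmse)

    def test_same_seed_reproduces_metrics(self):
        X, y = _linear_data(n=20, seed=3)
        r1 = cross_validate(BPNNConfig(seed=1), X, y, seed=9)
        r2 = cross_validate(BPNNConfig(seed=1), X, y, seed=9)
        assert r1 == r2

    def test_fold_assignment_is_balanced(self):
        labels = fold_assignment(23, 5, seed=0)
        counts = np.bincount(labels)
        assert counts.max() - counts.min() <= 1

    def test_invalid_fold_count_rejected(self):
        X, y = _linear_data(n=10)
        with pytest.raises(ValueError):
            cross_validate(BPNNConfig(), X, y, folds=1)
        with pytest.raises(ValueError):
            cross_validate(BPNNConfig(), X, y, folds=11)


class TestRepeatRuns:
    def test_deterministic_procedure_has_zero_variance(self):
        stats = repeat_runs(lambda seed: {"m": 1.25}, n_runs=5, master_seed=0)
        assert stats.variance["m"] == 0.0
        assert stats.mean["m"] == 1.25
        assert stats.n_runs == 5

    def test_two_run_closed_form(self):
        outputs = iter([3.0, 7.0])
        stats = repeat_runs(
            lambda seed: {"m": next(outputs)}, n_runs=2, master_seed=1
        )
        assert stats.mean["m"] == pytest.approx(5.0)  # (a+b)/2
        assert stats.variance["m"] == pytest.approx((3.0 - 7.0) ** 2 / 2)
        assert stats.sd["m"] == pytest.approx(abs(3.0 - 7.0) / np.sqrt(2))

    def test_fixed_master_seed_reproduces_stats(self):
        def proc(seed):
            rng = np.random.default_rng(seed)
            return {"m": float(rng.normal())}

        s1 = repeat_runs(proc, n_runs=8, master_seed=4)
        s2 = repeat_runs(proc, n_runs=8, master_seed=4)
        assert s1.values.equals(s2.values)

    def test_derived_seeds_are_distinct_31_bit(self):
        seeds = derive_seeds(0, 100)
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2**31 for s in seeds)
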