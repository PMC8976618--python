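import numpy as np
import pytest

from gelfeat.ica import (
    bss_demo,
    evaluation_factors,
    fastica,
    fit_ica_features,
    load_model,
    match_sources,
    save_model,
    select_features,
    whiten,
)
from gelfeat.synthetic import generate_bss_signals
from tests.conftest import random_dataset


class TestWhiten:
    def test_identity_covariance_exact(self, rng):
        X = rng.standard_normal((6, 40)) * np.array([5, 3, 1, 1, 0.5, 0.1])[:, None]
        Z, _ = whiten(X)
        cov = (Z @ Z.T) / Z.shape[1]
        assert np.allclose(cov, np.eye(Z.shape[0]), atol=1e-8)
        assert np.allclose(Z.mean(axis=1), 0.0, atol=1e-10)

    def test_correlated_gaussian_cloud(self):
        r = np.random.default_rng(0)
        cov = np.array([[1.0, 0.9], [0.9, 1.0]])
        X = np.linalg.cholesky(cov) @ r.standard_normal((2, 5000))
        Z, _ = whiten(X)
        sample_cov = np.cov(Z)  # oracle estimate, 1/(n-1) scaling
        assert np.allclose(sample_cov, np.eye(2), atol=5e-2)

    def test_rank_one_data_collapses_to_one_dimension(self, rng):
        direction = rng.standard_normal(3)
        X = np.outer(direction, rng.standard_normal(50))
        Z, _ = whiten(X)
        assert Z.shape[0] == 1

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="zero-variance"):
            whiten(np.ones((4, 10)))

    def test_inverse_round_trip(self, rng):
        X = rng.standard_normal((5, 30))
        Z, w = whiten(X)
        assert np.allclose(w.inverse(Z), X, atol=1e-8)


class TestFastICA:
    def _two_uniform_sources(self, n=4000, seed=0):
        r = np.random.default_rng(seed)
        S = r.uniform(-np.sqrt(3), np.sqrt(3), size=(2, n))
        A = np.array([[1.0, 0.6], [0.4, 1.0]])
        return S, A @ S

    def test_recovers_two_uniform_sources(self):
        S, X = self._two_uniform_sources()
        Z, _ = whiten(X)
        W, info = fastica(Z, seed=0)
        corr, _ = match_sources(S, W @ Z)
        assert np.all(corr >= 0.99)
        assert info["converged"]

    def test_single_component_sign_recovery(self):
        r = np.random.default_rng(3)
        s = r.uniform(-1, 1, size=(1, 3000))
        Z, _ = whiten(s * 2.0 + 1.0)
        W, _ = fastica(Z, n_components=1)
        assert np.isclose(abs(W[0, 0]), 1.0, atol=1e-6)

    def test_gaussian_data_flagged_unconverged(self):
        r = np.random.default_rng(0)
        Z, _ = whiten(r.standard_normal((5, 3000)))
        _, info = fastica(Z, seed=0)
        assert not info["converged"]
        assert info["iterations"] == 200

    def test_unmixing_rows_orthonormal(self):
        _, X = self._two_uniform_sources(seed=5)
        Z, _ = whiten(X)
        W, _ = fastica(Z, seed=1)
        assert np.allclose(W @ W.T, np.eye(2), atol=1e-6)

    def test_random_init_seeded_determinism(self):
        _, X = self._two_uniform_sources(seed=2)
        Z, _ = whiten(X)
        W1, _ = fastica(Z, seed=42, init="random")
        W2, _ = fastica(Z, seed=42, init="random")
        assert np.array_equal(W1, W2)

    def test_matches_sklearn_reference(self):
        sklearn = pytest.importorskip("sklearn.decomposition")
        S, X = self._two_uniform_sources(seed=7)
        Z, _ = whiten(X)
        W, _ = fastica(Z, seed=0)
        ours, _ = match_sources(S, W @ Z)
        ref = sklearn.FastICA(n_components=2, random_state=0, whiten="unit-variance")
        Y_ref = ref.fit_transform(X.T).T
        theirs, _ = match_sources(S, Y_ref)
        assert np.all(ours >= 0.99) and np.all(theirs >= 0.99)

    def test_bad_nonlinearity_and_component_count(self, rng):
        Z, _ = whiten(rng.standard_normal((3, 100)))
        with pytest.raises(ValueError, match="nonlinearity"):
            fastica(Z, nonlinearity="cubic")
        with pytest.raises(ValueError, match="exceeds"):
            fastica(Z, n_components=10)


class TestBSSDemo:
    def test_all_sources_recovered(self):
        S, X, Y, report = bss_demo(2000, seed=0)
        assert S.shape == X.shape == Y.shape == (4, 2000)
        assert report["all_above_095"]
        assert np.all(report["matched_correlations"] >= 0.95)

    def test_identity_mixing_reduces_to_rotation_recovery(self):
        S = generate_bss_signals(2000, seed=4)
        Z, _ = whiten(S, n_components=4)
        W, _ = fastica(Z, seed=4)
        corr, _ = match_sources(S, W @ Z)
        assert np.all(corr >= 0.99)

    def test_status_stable_across_seeds(self):
        statuses = {bss_demo(2000, seed=s)[3]["all_above_095"] for s in (3, 11)}
        assert statuses == {True}

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            bss_demo(100, seed=0)


class TestImageFeatures:
    def test_training_projections_have_unit_variance(self, gel_dataset_small):
        model = fit_ica_features(gel_dataset_small, n_components=5, seed=0)
        Y = model.transform(gel_dataset_small.to_matrix())
        variances = (Y**2).mean(axis=1) - Y.mean(axis=1) ** 2
        assert np.allclose(variances, 1.0, atol=1e-6)

    def test_mean_image_maps_to_zero(self, gel_dataset_small):
        model = fit_ica_features(gel_dataset_small, n_components=5, seed=0)
        y = model.transform(model.whitener.mean[:, None])
        assert np.allclose(y, 0.0, atol=1e-8)

    def test_reconstruction_residual_bounded_by_truncation(self, gel_dataset_small):
        X = gel_dataset_small.to_matrix()
        model = fit_ica_features(gel_dataset_small, n_components=8, seed=0)
        recon = model.reconstruct(model.transform(X))
        residual = np.mean(np.sum((X - recon) ** 2, axis=0))
        Xc = X - X.mean(axis=1, keepdims=True)
        total_var = np.sum(Xc**2) / X.shape[1]
        retained_var = np.sum(model.whitener.scales**2)
        floor = total_var - retained_var
        assert residual <= floor + 1e-6

    def test_seeded_fit_bit_identical(self, gel_dataset_small):
        m1 = fit_ica_features(gel_dataset_small, n_components=4, seed=9)
        m2 = fit_ica_features(gel_dataset_small, n_components=4, seed=9)
        assert np.array_equal(m1.unmixing, m2.unmixing)
        assert np.array_equal(m1.mixing_estimate, m2.mixing_estimate)

    def test_loadings_scale_transform_by_mixing_norms(self, gel_dataset_small):
        model = fit_ica_features(gel_dataset_small, n_components=4, seed=0)
        X = gel_dataset_small.to_matrix()[:, :3]
        expected = model.transform(X) * model.loading_scales[:, None]
        assert np.allclose(model.loadings(X), expected)

    def test_persistence_round_trip(self, tmp_path, gel_dataset_small):
        model = fit_ica_features(gel_dataset_small, n_components=4, seed=2)
        path = tmp_path / "ica.npz"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.unmixing, model.unmixing)
        X = gel_dataset_small.to_matrix()[:, :2]
        assert np.allclose(back.transform(X), model.transform(X))


class TestEvaluationFactors:
    def test_hand_enumerated_two_class_case(self):
        F = np.array([[0.0], [2.0], [10.0], [12.0]])
        t = evaluation_factors(F, labels=["a", "a", "b", "b"])
        assert t.U[0] == pytest.approx(2.0)
        assert t.V[0] == pytest.approx(10.0)
        assert t.beta[0] == pytest.approx(0.2)

    def test_constant_within_class_feature_scores_zero(self):
        F = np.array([[1.0], [1.0], [5.0], [5.0]])
        t = evaluation_factors(F, labels=["a", "a", "b", "b"])
        assert t.U[0] == 0.0 and t.beta[0] == 0.0

    def test_degenerate_feature_gets_infinity(self):
        F = np.ones((4, 1))
        t = evaluation_factors(F, labels=["a", "a", "b", "b"])
        assert np.isinf(t.beta[0])

    def test_unbalanced_classes_rejected(self):
        with pytest.raises(ValueError, match="balanced"):
            evaluation_factors(np.zeros((3, 1)), labels=["a", "a", "b"])

    def test_explicit_m_n_grouping(self):
        F = np.array([[0.0], [2.0], [10.0], [12.0]])
        t = evaluation_factors(F, M=2, N=2)
        assert t.beta[0] == pytest.approx(0.2)

    def test_beta_strictly_decreases_with_separation(self):
        r = np.random.default_rng(5)
        betas = []
        base = r.standard_normal((20, 1))
        labels = ["a"] * 10 + ["b"] * 10
        for sep in (0.5, 2.0, 8.0):
            F = base.copy()
            F[10:] += sep
            betas.append(evaluation_factors(F, labels=labels).beta[0])
        assert betas[0] > betas[1] > betas[2]

    def test_select_features_order_statistics(self):
        from gelfeat.ica import FeatureScoreTable

        beta = np.array([0.5, 0.1, 0.3])
        t = FeatureScoreTable(
            U=beta, V=np.ones(3), beta=beta,
            selected=np.argsort(beta, kind="stable"),
        )
        assert set(select_features(t, 2).tolist()) == {1, 2}
        assert set(select_features(t, 3).tolist()) == {0, 1, 2}
        with pytest.raises(ValueError):
            select_features(t, 4)

    def test_csv_export(self, tmp_path):
        F = np.array([[0.0], [2.0], [10.0], [12.0]])
        t = evaluation_factors(F, labels=["a", "a", "b", "b"])
        path = tmp_path / "scores.csv"
        t.to_csv(path)
        lines = path.read_text().strip().splitlines()
        assert lines[0] == "feature_index,U,V,beta,selected"
        assert len(lines) == 2
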