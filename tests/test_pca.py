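import numpy as np
import pytest

from gelfeat.pca import (
    eig_small_sample,
    feature_subimages,
    fit_pca,
    load_model,
    mean_vector,
    project,
    project_matrix,
    reconstruct,
    reconstruction_mse_min,
    save_model,
)
from tests.conftest import random_dataset


def dense_covariance_eig(Xc):
    """Oracle: eigendecomposition of the full mn x mn covariance matrix."""
    M = Xc.shape[1]
    C = (Xc @ Xc.T) / M
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    return evals[order], evecs[:, order]


class TestMeanVector:
    def test_midpoint(self):
        X = np.array([[0.0, 2.0], [0.0, 2.0]])
        assert np.array_equal(mean_vector(X), [1.0, 1.0])

    def test_single_column_identity(self, rng):
        v = rng.uniform(0, 1, 8)
        assert np.array_equal(mean_vector(v[:, None]), v)

    def test_matches_direct_summation(self, rng):
        X = rng.uniform(0, 1, (8, 5))
        oracle = sum(X[:, i] for i in range(5)) / 5
        assert np.allclose(mean_vector(X), oracle, atol=1e-12)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mean_vector(np.empty((4, 0)))


class TestEigSmallSample:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_dense_eigendecomposition(self, seed):
        r = np.random.default_rng(seed)
        X = r.standard_normal((16, 3))
        Xc = X - X.mean(axis=1, keepdims=True)
        evals, U = eig_small_sample(Xc)
        evals_o, U_o = dense_covariance_eig(Xc)
        k = evals.size
        assert np.allclose(evals, evals_o[:k], rtol=1e-8, atol=1e-12)
        for i in range(k):
            sign = np.sign(U_o[:, i] @ U[:, i])
            assert np.allclose(U[:, i], sign * U_o[:, i], atol=1e-8)

    def test_zero_matrix_gives_empty_spectrum(self):
        evals, U = eig_small_sample(np.zeros((10, 4)))
        assert evals.size == 0 and U.shape == (10, 0)

    def test_rank_one_input(self, rng):
        u = rng.standard_normal(12)
        v = np.array([1.0, -1.0, 2.0, -2.0])  # zero-mean weights
        X = np.outer(u, v)
        evals, _ = eig_small_sample(X)
        assert evals.size == 1

    def test_sign_convention_largest_entry_positive(self, rng):
        X = rng.standard_normal((16, 5))
        _, U = eig_small_sample(X - X.mean(axis=1, keepdims=True))
        for i in range(U.shape[1]):
            assert U[np.argmax(np.abs(U[:, i])), i] > 0

    def test_variance_accounting(self, rng):
        X = rng.standard_normal((20, 8))
        Xc = X - X.mean(axis=1, keepdims=True)
        evals, _ = eig_small_sample(Xc)
        trace_C = np.trace(Xc @ Xc.T) / Xc.shape[1]
        assert np.isclose(evals.sum(), trace_C, rtol=1e-8)


class TestFitProject:
    def test_rank_bound_two_images(self, rng):
        ds = random_dataset(rng, n_classes=1, per_class=2, shape=(6, 6))
        model = fit_pca(ds, p=1)
        assert model.retained == 1
        with pytest.raises(ValueError, match="rank"):
            fit_pca(ds, p=2)

    def test_basis_orthonormal(self, rng):
        ds = random_dataset(rng, per_class=6)
        model = fit_pca(ds)
        gram = model.basis.T @ model.basis
        assert np.allclose(gram, np.eye(model.retained), atol=1e-8)

    def test_mean_image_projects_to_zero(self, rng):
        ds = random_dataset(rng, per_class=4)
        model = fit_pca(ds)
        fv = project(model, model.mean)
        assert np.allclose(fv.values, 0.0, atol=1e-10)

    def test_basis_direction_recovers_coefficient(self, rng):
        ds = random_dataset(rng, per_class=6)
        model = fit_pca(ds)
        c = 0.37
        fv = project(model, model.mean + c * model.basis[:, 0])
        expected = np.zeros(model.retained)
        expected[0] = c
        assert np.allclose(fv.values, expected, atol=1e-10)

    def test_projection_matches_naive_loop(self, rng):
        ds = random_dataset(rng, per_class=5)
        model = fit_pca(ds)
        x = rng.uniform(0, 1, model.mean.size)
        naive = np.array(
            [model.basis[:, i] @ (x - model.mean) for i in range(model.retained)]
        )
        assert np.allclose(project(model, x).values, naive, atol=1e-10)

    def test_shape_mismatch_errors(self, rng, gel_dataset_small):
        model = fit_pca(gel_dataset_small)
        from gelfeat.image_io import ImageSample

        bad = ImageSample(pixels=np.zeros((8, 8)), label="x", id="x/0")
        with pytest.raises(ValueError, match="shape"):
            project(model, bad)

    def test_training_features_are_decorrelated(self, rng):
        ds = random_dataset(rng, per_class=8, shape=(6, 6))
        model = fit_pca(ds)
        Y = project_matrix(model, ds.to_matrix())
        cov = (Y @ Y.T) / Y.shape[1]
        off = cov - np.diag(np.diag(cov))
        assert np.abs(off).max() < 1e-8


class TestReconstruction:
    def test_tail_sum_examples(self):
        assert reconstruction_mse_min([4.0, 2.0, 1.0], 2) == 1.0
        assert reconstruction_mse_min([4.0, 2.0, 1.0], 3) == 0.0

    def test_out_of_range_p(self):
        with pytest.raises(ValueError):
            reconstruction_mse_min([1.0], 2)

    def test_equals_measured_residual_at_every_p(self, rng):
        ds = random_dataset(rng, per_class=6, shape=(5, 5))
        model = fit_pca(ds)
        X = ds.to_matrix()
        Y = project_matrix(model, X)
        for p in range(model.retained + 1):
            recon = model.mean[:, None] + model.basis[:, :p] @ Y[:p]
            measured = np.mean(np.sum((X - recon) ** 2, axis=0))
            assert np.isclose(
                measured, reconstruction_mse_min(model.eigenvalues, p), atol=1e-8
            )


class TestFeatureSubimages:
    def test_count_order_and_range(self, gel_dataset_small):
        model = fit_pca(gel_dataset_small, p=6)
        imgs = feature_subimages(model, 6)
        assert len(imgs) == 6
        for img, col in zip(imgs, model.basis.T):
            assert img.shape == gel_dataset_small.image_shape
            assert np.isclose(img.min(), 0.0) and np.isclose(img.max(), 1.0)
            # rescale is affine in the basis column
            flat = img.reshape(-1)
            rescaled = (col - col.min()) / (col.max() - col.min())
            assert np.allclose(flat, rescaled, atol=1e-12)

    def test_k_beyond_retained_errors(self, gel_dataset_small):
        model = fit_pca(gel_dataset_small, p=2)
        with pytest.raises(ValueError):
            feature_subimages(model, 3)


class TestPersistence:
    def test_round_trip(self, tmp_path, rng):
        ds = random_dataset(rng, per_class=5)
        model = fit_pca(ds, p=3)
        path = tmp_path / "pca.npz"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.mean, model.mean)
        assert np.array_equal(back.basis, model.basis)
        assert np.array_equal(back.eigenvalues, model.eigenvalues)
        assert back.image_shape == model.image_shape

    def test_load_validates_orthonormality(self, tmp_path, rng):
        ds = random_dataset(rng, per_class=5)
        model = fit_pca(ds, p=3)
        path = tmp_path / "pca.npz"
        model.basis[:, 0] *= 2.0  # corrupt after validation
        np.savez(
            path,
            format_version=np.array(1),
            mean=model.mean,
            eigenvalues=model.eigenvalues,
            basis=model.basis,
            image_shape=np.array(model.image_shape),
        )
        with pytest.raises(ValueError, match="orthonormal"):
            load_model(path)


def test_reconstruct_inverts_project_at_full_rank(rng):
    ds = random_dataset(rng, per_class=6, shape=(4, 4))
    model = fit_pca(ds)
    from gelfeat.image_io import vectorize

    x = vectorize(ds.samples[2])
    if model.retained == len(ds) - 1:  # generic full-rank case
        recon = reconstruct(model, project(model, x))
        # training samples lie in the affine span of the training set
        assert np.allclose(recon, x, atol=1e-8)
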