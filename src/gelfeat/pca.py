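"""PCA feature extraction with the small-sample covariance eigen trick.

For an (m*n) x M training matrix X of centered, vectorized images the
covariance C = (1/M) X X^T is mn x mn — far too large to eigendecompose
directly when images have thousands of pixels. Because X^T X (M x M) shares
C's nonzero spectrum, we diagonalize X^T X instead and map each eigenvector
eta back through X: X eta is an eigenvector of X X^T with the same
eigenvalue. Eigenvalues are scaled by 1/M to match C's population
normalization, and eigenvectors are normalized to unit length.

The minimum mean squared reconstruction error when keeping the top p
components is the tail eigenvalue sum  eps_min = sum_{i>p} lambda_i.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from gelfeat.image_io import ImageDataset, ImageSample, devectorize, vectorize

__all__ = [
    "PCAModel",
    "FeatureVector",
    "mean_vector",
    "eig_small_sample",
    "fit_pca",
    "project",
    "reconstruct",
    "reconstruction_mse_min",
    "feature_subimages",
    "save_model",
    "load_model",
]

# eigenvalues below this fraction of the leading one are numerical noise
_RANK_TOL = 1e-10
_ORTHO_TOL = 1e-8


@dataclass
class PCAModel:
    """Mean, spectrum and orthonormal projection basis of a PCA fit.

    ``basis`` has one column per retained component, columns orthonormal and
    ordered by non-increasing eigenvalue. ``eigenvalues`` stores the *full*
    retained-rank spectrum so reconstruction-error accounting is possible for
    any p; ``retained`` is the number of basis columns kept for projection.
    """

    mean: np.ndarray
    eigenvalues: np.ndarray
    basis: np.ndarray
    image_shape: tuple[int, int]

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=np.float64)
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=np.float64)
        self.basis = np.asarray(self.basis, dtype=np.float64)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted non-increasing")
        if np.any(self.eigenvalues < 0):
            raise ValueError("negative eigenvalue after clamping")
        gram = self.basis.T @ self.basis
        if not np.allclose(gram, np.eye(self.basis.shape[1]), atol=_ORTHO_TOL):
            raise ValueError("basis columns are not orthonormal")

    @property
    def retained(self) -> int:
        return self.basis.shape[1]


@dataclass(frozen=True)
class FeatureVector:
    """Projection coefficients of one image in a model's subspace."""

    values: np.ndarray
    model_id: str


def mean_vector(X: np.ndarray) -> np.ndarray:
    """Arithmetic mean of the columns of X (the average image vector)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValueError("X must be a 2-D matrix with at least one column")
    return X.mean(axis=1)


def _fix_signs(U: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-magnitude entry is positive."""
    if U.size == 0:
        return U
    idx = np.argmax(np.abs(U), axis=0)
    signs = np.sign(U[idx, np.arange(U.shape[1])])
    signs[signs == 0] = 1.0
    return U * signs


def eig_small_sample(X_centered: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenpairs of C = (1/M) X X^T via the M x M Gram matrix X^T X.

    Returns ``(eigenvalues, eigenvectors)`` sorted by descending eigenvalue,
    eigenvectors as unit-norm columns. Zero-variance directions (eigenvalues
    below ``1e-10 * lambda_1``) are discarded; an all-zero input yields an
    empty spectrum.
    """
    X = np.asarray(X_centered, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("X_centered must have at least 2 columns")
    M = X.shape[1]
    gram = X.T @ X
    evals, etas = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    etas = etas[:, order]
    if evals.size == 0 or evals[0] <= 0.0:
        return np.empty(0), np.empty((X.shape[0], 0))
    keep = evals > _RANK_TOL * evals[0]
    evals = evals[keep]
    etas = etas[:, keep]
    # map Gram eigenvectors into pixel space and unit-normalize:
    # ||X eta|| = sqrt(eta^T X^T X eta) = sqrt(lambda_gram)
    U = (X @ etas) / np.sqrt(evals)
    U = _fix_signs(U)
    return evals / M, U


def fit_pca(train: ImageDataset, p: int | None = None) -> PCAModel:
    """Fit a PCA model retaining the top ``p`` components.

    ``p=None`` keeps the full achievable rank. An explicit ``p`` above the
    achievable rank (at most M_train - 1 after centering, less for
    degenerate data) raises, reporting the rank.
    """
    X = train.to_matrix()
    mu = mean_vector(X)
    evals, U = eig_small_sample(X - mu[:, None])
    rank = evals.size
    if p is None:
        p = rank
    elif p > rank:
        raise ValueError(f"requested p={p} exceeds achievable rank {rank}")
    return PCAModel(
        mean=mu,
        eigenvalues=evals,
        basis=U[:, :p],
        image_shape=train.image_shape,
    )


def project(model: PCAModel, sample: ImageSample | np.ndarray) -> FeatureVector:
    """Project an image onto the retained basis: y = U^T (chi - mu)."""
    if isinstance(sample, ImageSample):
        if sample.shape != model.image_shape:
            raise ValueError(
                f"sample shape {sample.shape} != model shape {model.image_shape}"
            )
        chi = vectorize(sample)
    else:
        chi = np.asarray(sample, dtype=np.float64).reshape(-1)
        if chi.size != model.mean.size:
            raise ValueError("vector length does not match model")
    return FeatureVector(values=model.basis.T @ (chi - model.mean), model_id="pca")


def project_matrix(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project columns of an (m*n) x K matrix; returns retained x K."""
    return model.basis.T @ (np.asarray(X, dtype=np.float64) - model.mean[:, None])


def reconstruct(model: PCAModel, feature: FeatureVector | np.ndarray) -> np.ndarray:
    """Map projection coefficients back to pixel space: mu + U y."""
    y = feature.values if isinstance(feature, FeatureVector) else np.asarray(feature)
    return model.mean + model.basis[:, : y.size] @ y


def reconstruction_mse_min(eigenvalues: np.ndarray, p: int) -> float:
    """Minimum mean squared reconstruction error keeping p components.

    Equals the sum of discarded eigenvalues; 0 at full retention.
    """
    lam = np.asarray(eigenvalues, dtype=np.float64)
    if p < 0 or p > lam.size:
        raise ValueError(f"p={p} outside [0, {lam.size}]")
    return float(lam[p:].sum())


def feature_subimages(model: PCAModel, k: int) -> list[np.ndarray]:
    """The first k basis vectors reshaped to images, rescaled to [0, 1].

    Ordered by descending eigenvalue; the leading sub-images carry the most
    variance and look the least blurred.
    """
    if k > model.retained:
        raise ValueError(f"k={k} exceeds retained dimension {model.retained}")
    out = []
    for i in range(k):
        img = devectorize(model.basis[:, i], *model.image_shape)
        lo, hi = img.min(), img.max()
        out.append((img - lo) / (hi - lo) if hi > lo else np.zeros_like(img))
    return out


_FORMAT_VERSION = 1


def save_model(model: PCAModel, path: str | Path) -> None:
    """Persist a PCA model to a single .npz archive."""
    np.savez(
        path,
        format_version=np.array(_FORMAT_VERSION),
        mean=model.mean,
        eigenvalues=model.eigenvalues,
        basis=model.basis,
        image_shape=np.array(model.image_shape),
    )


def load_model(path: str | Path) -> PCAModel:
    """Load a persisted PCA model, validating orthonormality on read."""
    with np.load(path) as z:
        if int(z["format_version"]) != _FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        return PCAModel(
            mean=z["mean"],
            eigenvalues=z["eigenvalues"],
            basis=z["basis"],
            image_shape=tuple(int(v) for v in z["image_shape"]),
        )
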