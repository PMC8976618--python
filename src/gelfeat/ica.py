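"""FastICA feature extraction and the intra/inter-class evaluation factor.

Blind source separation model: observed signals X are an unknown linear mix
X = A S of statistically independent, zero-mean sources S. Because sums of
independent variables drift toward Gaussianity (central limit theorem), the
unmixing matrix W that makes the outputs Y = W X maximally non-Gaussian
recovers the sources up to permutation and scale. FastICA finds W by a
fixed-point iteration on whitened data with symmetric orthogonalization, so
all components are estimated in parallel.

For image features, vectorized images are the observations: FastICA learns a
basis of independent source images and each image is represented by its
coordinates in that basis. Because FastICA returns components in arbitrary
order, features are ranked afterwards by the evaluation factor

    beta_j = U_j / V_j,

the ratio of the mean within-class distance U_j of feature j to its mean
between-class distance V_j. Small beta marks a feature whose classes are
tight and far apart — the most discriminative ones are the k smallest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from gelfeat.image_io import ImageDataset, ImageSample, vectorize

__all__ = [
    "Whitener",
    "ICAModel",
    "FeatureScoreTable",
    "whiten",
    "fastica",
    "bss_demo",
    "fit_ica_features",
    "evaluation_factors",
    "select_features",
    "save_model",
    "load_model",
]


@dataclass
class Whitener:
    """Affine transform to zero mean and identity covariance.

    ``transform`` maps d-dimensional observations (columns) to r <= d
    whitened coordinates; rank-deficient directions are dropped. ``scales``
    holds the retained standard deviations so the inverse map is available.
    """

    mean: np.ndarray
    components: np.ndarray  # r x d, rows are unit principal directions
    scales: np.ndarray  # r, standard deviations along components

    def transform(self, X: np.ndarray) -> np.ndarray:
        Xc = np.asarray(X, dtype=np.float64) - self.mean[:, None]
        return (self.components @ Xc) / self.scales[:, None]

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return self.components.T @ (Z * self.scales[:, None]) + self.mean[:, None]

    @property
    def n_components(self) -> int:
        return self.components.shape[0]


def whiten(
    X: np.ndarray,
    n_components: int | None = None,
    var_ratio: float = 0.999,
) -> tuple[np.ndarray, Whitener]:
    """PCA-whiten observations (columns of X) to zero mean, unit covariance.

    Keeps the smallest number of principal directions covering ``var_ratio``
    of the variance, or exactly ``n_components`` when given (capped at the
    numerical rank). Covariance uses the population 1/M normalization.
    """
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 observations to whiten")
    M = X.shape[1]
    mu = X.mean(axis=1)
    Xc = X - mu[:, None]
    # small-sample route: spectrum of (1/M) Xc Xc^T via the M x M Gram matrix
    gram = Xc.T @ Xc
    evals, etas = np.linalg.eigh(gram)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    etas = etas[:, order]
    if evals.size == 0 or evals[0] <= 0.0:
        raise ValueError("zero-variance input cannot be whitened")
    keep = evals > 1e-10 * evals[0]
    evals, etas = evals[keep], etas[:, keep]
    if n_components is not None:
        r = min(n_components, evals.size)
    else:
        cum = np.cumsum(evals) / evals.sum()
        r = int(np.searchsorted(cum, var_ratio) + 1)
    evals, etas = evals[:r], etas[:, :r]
    directions = (Xc @ etas) / np.sqrt(evals)  # unit-norm columns
    w = Whitener(
        mean=mu,
        components=directions.T,
        scales=np.sqrt(evals / M),
    )
    return w.transform(X), w


def _logcosh(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    g = np.tanh(u)
    return g, 1.0 - g**2


def _gauss(u: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    e = np.exp(-(u**2) / 2.0)
    return u * e, (1.0 - u**2) * e


_NONLINEARITIES = {"logcosh": _logcosh, "gauss": _gauss}


def _sym_decorrelate(W: np.ndarray) -> np.ndarray:
    """W <- (W W^T)^{-1/2} W, the symmetric orthogonalization step."""
    s, u = np.linalg.eigh(W @ W.T)
    s = np.clip(s, 1e-12, None)
    return (u / np.sqrt(s)) @ u.T @ W


@dataclass
class ICAModel:
    """Whitener plus unmixing matrix estimated by FastICA.

    ``unmixing`` (c x r) acts on whitened coordinates; rows are orthonormal
    because of the symmetric decorrelation. ``mixing_estimate`` maps
    component coordinates back toward observation space (pseudo-inverse of
    the composite unmixing transform).
    """

    whitener: Whitener
    unmixing: np.ndarray
    mixing_estimate: np.ndarray
    convergence_info: dict = field(default_factory=dict)
    image_shape: tuple[int, int] | None = None

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def transform(self, X: np.ndarray) -> np.ndarray:
        """Component coordinates (c x K) of observation columns."""
        return self.unmixing @ self.whitener.transform(X)

    def transform_sample(self, sample: ImageSample) -> np.ndarray:
        if self.image_shape is not None and sample.shape != self.image_shape:
            raise ValueError(
                f"sample shape {sample.shape} != model shape {self.image_shape}"
            )
        return self.transform(vectorize(sample)[:, None])[:, 0]

    @property
    def loading_scales(self) -> np.ndarray:
        """Norms of the estimated mixing columns (base-image strengths)."""
        return np.linalg.norm(self.mixing_estimate, axis=0)

    def loadings(self, X: np.ndarray) -> np.ndarray:
        """Combination coefficients over unit-norm base images.

        A centered image decomposes as  x - mu = sum_i b_i (a_i / ||a_i||)
        with a_i the estimated mixing columns, so b_i = y_i ||a_i|| where y
        are the unit-variance component coordinates. Unlike ``transform``,
        these coefficients keep the strength hierarchy of the base images,
        which is what a distance-based classifier should compare.
        """
        return self.transform(X) * self.loading_scales[:, None]

    def reconstruct(self, Y: np.ndarray) -> np.ndarray:
        """Approximate observations from component coordinates."""
        return self.mixing_estimate @ Y + self.whitener.mean[:, None]


def fastica(
    Z: np.ndarray,
    n_components: int | None = None,
    nonlinearity: str = "logcosh",
    tol: float = 1e-4,
    max_iter: int = 200,
    seed: int = 0,
    init: str = "identity",
) -> tuple[np.ndarray, dict]:
    """Fixed-point FastICA on pre-whitened data (components x samples).

    Returns the orthonormal unmixing matrix W (c x r) and a convergence
    report. Non-convergence is flagged in the report, never raised: on data
    with no non-Gaussian structure the objective is flat and the iteration
    cannot settle, which is an identifiability limit rather than an error.

    ``init='identity'`` (default) starts the iteration from the whitened
    principal axes, which makes the fit a deterministic function of the
    data and keeps refits on overlapping training sets in nearby optima;
    ``init='random'`` uses a seeded random orthogonal start.
    """
    Z = np.asarray(Z, dtype=np.float64)
    r, M = Z.shape
    c = r if n_components is None else n_components
    if c > r:
        raise ValueError(f"n_components={c} exceeds whitened dimension {r}")
    if nonlinearity not in _NONLINEARITIES:
        raise ValueError(
            f"unknown nonlinearity {nonlinearity!r}; choose from "
            f"{sorted(_NONLINEARITIES)}"
        )
    g_fn = _NONLINEARITIES[nonlinearity]
    if init == "identity":
        W = np.eye(c, r)
    elif init == "random":
        rng = np.random.default_rng(seed)
        W = _sym_decorrelate(rng.standard_normal((c, r)))
    else:
        raise ValueError(f"unknown init {init!r}; choose 'identity' or 'random'")
    residual = np.inf
    for it in range(1, max_iter + 1):
        U = W @ Z
        G, Gp = g_fn(U)
        W_new = (G @ Z.T) / M - Gp.mean(axis=1)[:, None] * W
        W_new = _sym_decorrelate(W_new)
        # rotation-invariant residual: rows should reproduce themselves
        residual = float(np.max(np.abs(np.abs(np.sum(W_new * W, axis=1)) - 1.0)))
        W = W_new
        if residual < tol:
            break
    info = {
        "iterations": it,
        "residual": residual,
        "converged": residual < tol,
        "nonlinearity": nonlinearity,
    }
    return W, info


def fit_ica_features(
    train: ImageDataset | np.ndarray,
    n_components: int | None = None,
    seed: int = 0,
    nonlinearity: str = "logcosh",
    tol: float = 1e-4,
    max_iter: int = 200,
    var_ratio: float = 0.999,
    init: str = "identity",
) -> ICAModel:
    """Whiten vectorized training images and estimate independent components.

    ``n_components=None`` fits the default pool of min(100, rank)
    components — dimension sweeps then truncate this pool after ranking by
    the evaluation factor instead of refitting. The whitening keeps
    ``n_components`` principal directions (capped by rank); FastICA then
    rotates them to maximal non-Gaussianity. Identical seeds give
    bit-identical models.
    """
    if isinstance(train, ImageDataset):
        X = train.to_matrix()
        shape = train.image_shape
    else:
        X = np.asarray(train, dtype=np.float64)
        shape = None
    if n_components is None:
        n_components = 100
    Z, w = whiten(X, n_components=n_components, var_ratio=var_ratio)
    if w.n_components < n_components:
        n_components = w.n_components
    W, info = fastica(
        Z,
        n_components=n_components,
        nonlinearity=nonlinearity,
        tol=tol,
        max_iter=max_iter,
        seed=seed,
        init=init,
    )
    # composite unmix: y = W D^{-1/2} E^T (x - mu); its pseudo-inverse is
    # E D^{1/2} W^T because W has orthonormal rows
    mixing = w.components.T @ (w.scales[:, None] * W.T)
    return ICAModel(
        whitener=w,
        unmixing=W,
        mixing_estimate=mixing,
        convergence_info=info,
        image_shape=shape,
    )


def bss_demo(
    n_samples: int = 2000, seed: int = 0
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict]:
    """Blind-source-separation demonstration on four canonical signals.

    Generates sine, square, sawtooth and uniform-noise sources, mixes them
    with a random full-rank 4x4 matrix, unmixes with whiten + FastICA, and
    reports the permutation/sign-matched correlation per source.
    """
    from gelfeat.synthetic import generate_bss_signals

    if n_samples < 512:
        raise ValueError("need at least 512 samples for the demo")
    S = generate_bss_signals(n_samples, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    while True:
        A = rng.standard_normal((4, 4))
        if abs(np.linalg.det(A)) > 1e-2:
            break
    X = A @ S
    Z, w = whiten(X, n_components=4)
    W, info = fastica(Z, seed=seed)
    Y = W @ Z
    corr, perm = match_sources(S, Y)
    report = {
        "matched_correlations": corr,
        "permutation": perm,
        "all_above_095": bool(np.all(np.abs(corr) >= 0.95)),
        "convergence": info,
    }
    return S, X, Y, report


def match_sources(S: np.ndarray, Y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Greedy permutation/sign matching of recovered to true sources.

    Returns (matched absolute correlations per true source, permutation of
    recovered component indices).
    """
    from scipy.optimize import linear_sum_assignment

    k = S.shape[0]
    C = np.corrcoef(np.vstack([S, Y]))[:k, k:]
    row, col = linear_sum_assignment(-np.abs(C))
    corr = np.abs(C[row, col])
    return corr, col


@dataclass
class FeatureScoreTable:
    """Per-feature within-class distance U, between-class distance V,
    evaluation factor beta = U/V, and the selected index set."""

    U: np.ndarray
    V: np.ndarray
    beta: np.ndarray
    selected: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        import csv

        sel = set(self.selected.tolist())
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["feature_index", "U", "V", "beta", "selected"])
            for j in range(self.beta.size):
                writer.writerow(
                    [j, self.U[j], self.V[j], self.beta[j], int(j in sel)]
                )


def evaluation_factors(
    features: np.ndarray,
    labels: Sequence | None = None,
    M: int | None = None,
    N: int | None = None,
) -> FeatureScoreTable:
    """Score features by the ratio of within- to between-class spread.

    ``features`` is (samples x features). Classes must be balanced: M
    classes of N samples each (inferred from ``labels`` when given,
    otherwise ``M`` and ``N`` must be passed and rows must be grouped by
    class). For each feature j:

    * U_j — mean absolute difference over all ordered within-class sample
      pairs, averaged over classes: 1/(M N (N-1)) sum over classes and pairs.
    * V_j — mean absolute difference between per-class means over all
      ordered class pairs: 1/(M (M-1)) sum over pairs.
    * beta_j = U_j / V_j; a feature with no between-class separation
      (V_j = 0) gets +inf so it ranks last.
    """
    F = np.asarray(features, dtype=np.float64)
    if F.ndim != 2:
        raise ValueError("features must be (samples x features)")
    if labels is not None:
        labels = list(labels)
        if len(labels) != F.shape[0]:
            raise ValueError("labels length must match sample count")
        classes: dict = {}
        for i, lab in enumerate(labels):
            classes.setdefault(lab, []).append(i)
        sizes = {len(v) for v in classes.values()}
        if len(sizes) != 1:
            raise ValueError("classes must be balanced for the evaluation factor")
        N = sizes.pop()
        M = len(classes)
        groups = [np.array(v) for v in classes.values()]
    else:
        if M is None or N is None:
            raise ValueError("pass labels, or both M and N")
        if F.shape[0] != M * N:
            raise ValueError(f"expected {M}*{N} rows, got {F.shape[0]}")
        groups = [np.arange(i * N, (i + 1) * N) for i in range(M)]
    if N < 2:
        raise ValueError("need at least 2 samples per class")

    d = F.shape[1]
    U = np.zeros(d)
    class_means = np.zeros((M, d))
    for gi, idx in enumerate(groups):
        block = F[idx]  # N x d
        diffs = np.abs(block[:, None, :] - block[None, :, :])  # N x N x d
        U += diffs.sum(axis=(0, 1))  # ordered pairs, diagonal is zero
        class_means[gi] = block.mean(axis=0)
    U /= M * N * (N - 1)
    mean_diffs = np.abs(class_means[:, None, :] - class_means[None, :, :])
    V = mean_diffs.sum(axis=(0, 1)) / (M * (M - 1))

    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(V > 0, U / np.where(V > 0, V, 1.0), np.inf)
    beta = np.where((V == 0) & (U == 0), np.inf, beta)
    selected = np.argsort(beta, kind="stable")
    return FeatureScoreTable(U=U, V=V, beta=beta, selected=selected)


def select_features(table: FeatureScoreTable, k: int) -> np.ndarray:
    """Indices of the k smallest evaluation factors; ties by lower index."""
    if k > table.beta.size:
        raise ValueError(f"k={k} exceeds feature count {table.beta.size}")
    return table.selected[:k]


_FORMAT_VERSION = 1


def save_model(model: ICAModel, path: str | Path) -> None:
    """Persist an ICA model to a single .npz archive."""
    np.savez(
        path,
        format_version=np.array(_FORMAT_VERSION),
        mean=model.whitener.mean,
        components=model.whitener.components,
        scales=model.whitener.scales,
        unmixing=model.unmixing,
        mixing_estimate=model.mixing_estimate,
        image_shape=np.array(model.image_shape if model.image_shape else (0, 0)),
        converged=np.array(bool(model.convergence_info.get("converged", False))),
    )


def load_model(path: str | Path) -> ICAModel:
    """Load a persisted ICA model, validating row orthonormality on read."""
    with np.load(path) as z:
        if int(z["format_version"]) != _FORMAT_VERSION:
            raise ValueError("unsupported model archive version")
        W = z["unmixing"]
        if not np.allclose(W @ W.T, np.eye(W.shape[0]), atol=1e-6):
            raise ValueError("corrupt archive: unmixing rows not orthonormal")
        shape = tuple(int(v) for v in z["image_shape"])
        return ICAModel(
            whitener=Whitener(
                mean=z["mean"], components=z["components"], scales=z["scales"]
            ),
            unmixing=W,
            mixing_estimate=z["mixing_estimate"],
            convergence_info={"converged": bool(z["converged"])},
            image_shape=shape if shape != (0, 0) else None,
        )
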