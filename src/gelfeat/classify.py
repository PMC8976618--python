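"""Nearest-neighbor classification and the repeated-random-split harness.

The evaluation protocol: pick P training images per class at random, fit a
feature extractor on the training split, classify every remaining image
with the 1-nearest-neighbor rule, and report the recognition rate (percent
correct). Each configuration is repeated over independent random splits
(default 10) and the per-dimension mean over repeats is reported, sweeping
the feature dimension by truncating the fitted feature space.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from gelfeat import ica as _ica
from gelfeat import pca as _pca
from gelfeat import wavelet as _wavelet
from gelfeat.image_io import ImageDataset, SplitSpec, random_split
from gelfeat.subpattern import BlockGrid, classify_weighted_vote, fit_subpattern
from gelfeat.synthetic import OcclusionSpec, apply_occlusion

__all__ = [
    "ALGORITHMS",
    "ExperimentConfig",
    "ExperimentResult",
    "nearest_neighbor",
    "recognition_rate",
    "run_experiment",
    "export_csv",
    "export_json",
    "plot_result",
]

ALGORITHMS = ("pca", "wavelet_pca", "ica", "subpattern_ica")
_METRICS = ("euclidean", "cosine")


@dataclass(frozen=True)
class ExperimentConfig:
    """One benchmark configuration: algorithm, split size, dimension sweep."""

    algorithm: str
    P: int
    dims: tuple[int, ...]
    repeats: int = 10
    seed: int = 0
    distance_metric: str = "euclidean"
    grid: tuple[int, int] = (4, 4)  # subpattern only
    wavelet_name: str = "db2"  # wavelet_pca only
    use_beta_ordering: bool = True  # ica/subpattern component ordering
    occlude_test: OcclusionSpec | None = None

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(
                f"unknown algorithm {self.algorithm!r}; valid: {ALGORITHMS}"
            )
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        if not self.dims or list(self.dims) != sorted(self.dims):
            raise ValueError("dims must be nonempty and ascending")
        if self.distance_metric not in _METRICS:
            raise ValueError(
                f"unknown metric {self.distance_metric!r}; valid: {_METRICS}"
            )


@dataclass
class ExperimentResult:
    """Recognition rates from a repeated-random-split experiment.

    ``rates`` is (repeats x dims) in percent; ``mean_rates`` its per-dim
    arithmetic mean over repeats.
    """

    config: ExperimentConfig
    rates: np.ndarray
    mean_rates: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=np.float64)
        if np.any(self.rates < 0) or np.any(self.rates > 100):
            raise ValueError("recognition rates must lie in [0, 100]")
        self.mean_rates = self.rates.mean(axis=0)


def nearest_neighbor(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    query_feature: np.ndarray,
    metric: str = "euclidean",
) -> str:
    """Label of the closest training feature; ties by lowest index."""
    F = np.asarray(train_features, dtype=np.float64)
    q = np.asarray(query_feature, dtype=np.float64).reshape(1, -1)
    if F.ndim != 2 or F.shape[0] < 1:
        raise ValueError("need at least one training feature")
    if F.shape[1] != q.shape[1]:
        raise ValueError(
            f"feature dimension mismatch: train {F.shape[1]}, query {q.shape[1]}"
        )
    d = cdist(F, q, metric=metric)[:, 0]
    return train_labels[int(np.argmin(d))]


def _nn_batch(
    train_features: np.ndarray,
    train_labels: Sequence[str],
    queries: np.ndarray,
    metric: str,
) -> list[str]:
    d = cdist(np.asarray(queries), np.asarray(train_features), metric=metric)
    idx = np.argmin(d, axis=1)
    return [train_labels[i] for i in idx]


def recognition_rate(predicted: Sequence[str], truth: Sequence[str]) -> float:
    """Percentage of correct predictions."""
    if len(predicted) != len(truth) or len(truth) == 0:
        raise ValueError("predicted and truth must have equal nonzero length")
    correct = sum(p == t for p, t in zip(predicted, truth))
    return 100.0 * correct / len(truth)


def _beta_order(features_cols: np.ndarray, labels: list[str]) -> np.ndarray:
    """Component order by ascending evaluation factor (balanced training).

    The factor needs at least two samples per class; with P=1 training
    images the fit order is kept unchanged.
    """
    counts: dict[str, int] = {}
    for lab in labels:
        counts[lab] = counts.get(lab, 0) + 1
    if min(counts.values()) < 2 or len(set(counts.values())) != 1:
        return np.arange(features_cols.shape[0])
    table = _ica.evaluation_factors(features_cols.T, labels=labels)
    return table.selected


def _fit_and_rates(
    train: ImageDataset,
    test: ImageDataset,
    config: ExperimentConfig,
    repeat_seed: int,
) -> list[float]:
    """Fit the configured algorithm once at max dim, sweep by truncation."""
    dims = list(config.dims)
    max_dim = dims[-1]
    labels = train.labels()
    truth = test.labels()
    rates: list[float] = []

    if config.algorithm in ("pca", "wavelet_pca"):
        # fit at full rank; sweeping truncates leading components, and
        # requested dims beyond the achievable rank saturate at the rank
        if config.algorithm == "pca":
            model = _pca.fit_pca(train, p=None)
            train_F = _pca.project_matrix(model, train.to_matrix()).T
            test_F = np.vstack(
                [_pca.project(model, s).values for s in test]
            )
        else:
            model = _wavelet.fit_wavelet_pca(
                train, p=None, wavelet_name=config.wavelet_name
            )
            train_F = np.vstack(
                [_wavelet.project_wavelet(model, s).values for s in train]
            )
            test_F = np.vstack(
                [_wavelet.project_wavelet(model, s).values for s in test]
            )
        for d in dims:
            d_eff = min(d, train_F.shape[1])
            pred = _nn_batch(
                train_F[:, :d_eff], labels, test_F[:, :d_eff], config.distance_metric
            )
            rates.append(recognition_rate(pred, truth))

    elif config.algorithm == "ica":
        # fit the component pool once at the sweep maximum (capped at the
        # training rank); the beta ranking below orders the pool so each
        # sweep point keeps its d most discriminative components. The pool
        # must stay well below the training count: FastICA at near-full
        # rank degenerates to one-spike components that carry no class
        # information.
        model = _ica.fit_ica_features(train, n_components=max_dim, seed=repeat_seed)
        train_F = model.loadings(train.to_matrix())  # c x M
        if config.use_beta_ordering:
            order = _beta_order(train_F, labels)
            train_F = train_F[order]
        else:
            order = np.arange(train_F.shape[0])
        test_F = model.loadings(test.to_matrix())[order]
        for d in dims:
            d_eff = min(d, train_F.shape[0])
            pred = _nn_batch(
                train_F[:d_eff].T, labels, test_F[:d_eff].T, config.distance_metric
            )
            rates.append(recognition_rate(pred, truth))

    else:  # subpattern_ica
        model = fit_subpattern(
            train,
            grid=BlockGrid(*config.grid),
            n_components=max_dim,
            seed=repeat_seed,
            order_by_beta=config.use_beta_ordering,
        )
        for d in dims:
            pred = [
                classify_weighted_vote(model, s, dim=min(d, model.n_components))[0]
                for s in test
            ]
            rates.append(recognition_rate(pred, truth))
    return rates


def run_experiment(
    dataset: ImageDataset, config: ExperimentConfig
) -> ExperimentResult:
    """Run the repeated-random-split benchmark for one configuration.

    For each repeat: draw a P-per-class split from (seed, repeat_index),
    fit the algorithm at the largest requested dimension, truncate the
    fitted feature space for each dimension in the sweep, classify the test
    split by nearest neighbor, and record the recognition rate. Test-side
    occlusion, when configured, is applied to the test split only.
    """
    counts = dataset.class_counts()
    min_n = min(counts.values())
    if config.P >= min_n:
        raise ValueError(
            f"P={config.P} infeasible: smallest class has {min_n} samples"
        )
    all_rates = np.zeros((config.repeats, len(config.dims)))
    for rep in range(config.repeats):
        spec = SplitSpec(
            train_per_class=config.P, seed=config.seed, repeat_index=rep
        )
        train, test = random_split(dataset, spec)
        if config.occlude_test is not None:
            test = apply_occlusion(
                test, config.occlude_test, seed=config.seed + rep
            )
        repeat_seed = int((config.seed * 7919 + rep) % (2**31 - 1))
        all_rates[rep] = _fit_and_rates(train, test, config, repeat_seed)
    return ExperimentResult(config=config, rates=all_rates)


def export_csv(result: ExperimentResult, path: str | Path) -> Path:
    """Write per-repeat rates as (algorithm, P, dim, repeat, rate) rows."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["algorithm", "P", "dim", "repeat", "rate"])
        for rep in range(result.rates.shape[0]):
            for di, d in enumerate(result.config.dims):
                writer.writerow(
                    [
                        result.config.algorithm,
                        result.config.P,
                        d,
                        rep,
                        f"{result.rates[rep, di]:.6f}",
                    ]
                )
    return path


def export_json(result: ExperimentResult, path: str | Path) -> Path:
    """Write a JSON summary: config echo plus per-dimension mean rates."""
    path = Path(path)
    payload = {
        "algorithm": result.config.algorithm,
        "P": result.config.P,
        "repeats": result.config.repeats,
        "seed": result.config.seed,
        "distance_metric": result.config.distance_metric,
        "dims": list(result.config.dims),
        "mean_rates": [float(v) for v in result.mean_rates],
    }
    path.write_text(json.dumps(payload, indent=2))
    return path


def plot_result(
    results: Sequence[ExperimentResult], path: str | Path
) -> Path:
    """Recognition-rate-vs-dimension curves for one or more experiments."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for res in results:
        ax.plot(
            res.config.dims,
            res.mean_rates,
            marker="o",
            label=f"{res.config.algorithm} (P={res.config.P})",
        )
    ax.set_xlabel("feature dimension")
    ax.set_ylabel("recognition rate (%)")
    ax.set_ylim(0, 101)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
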