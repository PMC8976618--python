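"""Subpattern-ICA: block-wise independent feature extraction with adaptive
weighted voting.

Each image is tiled into a fixed grid of non-overlapping blocks; the
corresponding blocks across the training set form independent sub-models,
each fitted with FastICA. Because local image regions are not equally
reliable — occlusion, lighting, and texture changes hit some regions and
not others — every block receives an adaptive weight proportional to the
nearest-neighbor recognition rate its features achieve on their own. At
classification time each block votes for the class of its nearest training
sub-block, and the weighted vote decides the label. A corrupted region then
only costs its own (down-weighted) votes rather than polluting one global
feature vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from gelfeat.ica import ICAModel, evaluation_factors, fit_ica_features
from gelfeat.image_io import ImageDataset, ImageSample

__all__ = [
    "BlockGrid",
    "SubpatternModel",
    "partition_blocks",
    "assemble_blocks",
    "fit_subpattern",
    "adaptive_weights",
    "classify_weighted_vote",
]


@dataclass(frozen=True)
class BlockGrid:
    """A rows x cols grid of equal, non-overlapping blocks."""

    rows_of_blocks: int
    cols_of_blocks: int

    def __post_init__(self) -> None:
        if self.rows_of_blocks < 1 or self.cols_of_blocks < 1:
            raise ValueError("grid dimensions must be >= 1")

    @property
    def n_blocks(self) -> int:
        return self.rows_of_blocks * self.cols_of_blocks

    def block_shape(self, image_shape: tuple[int, int]) -> tuple[int, int]:
        m, n = image_shape
        if m % self.rows_of_blocks or n % self.cols_of_blocks:
            valid_r = [d for d in range(1, m + 1) if m % d == 0]
            valid_c = [d for d in range(1, n + 1) if n % d == 0]
            raise ValueError(
                f"image {image_shape} not divisible by grid "
                f"{self.rows_of_blocks}x{self.cols_of_blocks}; valid row "
                f"divisors {valid_r}, column divisors {valid_c}"
            )
        return m // self.rows_of_blocks, n // self.cols_of_blocks


def partition_blocks(image: np.ndarray, grid: BlockGrid) -> list[np.ndarray]:
    """Tile an image into row-major ordered blocks (copies)."""
    img = np.asarray(image, dtype=np.float64)
    br, bc = grid.block_shape(img.shape)
    blocks = []
    for i in range(grid.rows_of_blocks):
        for j in range(grid.cols_of_blocks):
            blocks.append(img[i * br : (i + 1) * br, j * bc : (j + 1) * bc].copy())
    return blocks


def assemble_blocks(blocks: list[np.ndarray], grid: BlockGrid) -> np.ndarray:
    """Inverse of :func:`partition_blocks`."""
    if len(blocks) != grid.n_blocks:
        raise ValueError(f"expected {grid.n_blocks} blocks, got {len(blocks)}")
    rows = [
        np.hstack(blocks[i * grid.cols_of_blocks : (i + 1) * grid.cols_of_blocks])
        for i in range(grid.rows_of_blocks)
    ]
    return np.vstack(rows)


def _block_seed(seed: int, block_index: int) -> int:
    # deterministic per-block stream, kept below 2**31
    return int((seed * 1_000_003 + block_index) % (2**31 - 1))


@dataclass
class SubpatternModel:
    """Per-block ICA sub-models, cached training features, and vote weights.

    ``block_features[b]`` is (n_components x M_train) for block b, with
    components ordered by ascending evaluation factor so truncating to the
    leading d rows keeps the most discriminative features. ``weights`` lie
    on the simplex (nonnegative, summing to one).
    """

    grid: BlockGrid
    block_models: list[ICAModel]
    block_features: list[np.ndarray]
    train_labels: list[str]
    classes: list[str]
    weights: np.ndarray
    image_shape: tuple[int, int]
    n_components: int

    def _block_query_features(self, sample: ImageSample | np.ndarray) -> list[np.ndarray]:
        px = sample.pixels if isinstance(sample, ImageSample) else np.asarray(sample)
        if px.shape != self.image_shape:
            raise ValueError(
                f"sample shape {px.shape} != model shape {self.image_shape}"
            )
        feats = []
        for b, blk in enumerate(partition_blocks(px, self.grid)):
            feats.append(
                self.block_models[b].loadings(blk.reshape(-1)[:, None])[:, 0]
            )
        return feats

    def predict(self, sample: ImageSample | np.ndarray, dim: int | None = None):
        return classify_weighted_vote(self, sample, dim=dim)


def fit_subpattern(
    train: ImageDataset,
    grid: BlockGrid = BlockGrid(4, 4),
    n_components: int | None = None,
    seed: int = 0,
    weight_eval: ImageDataset | None = None,
    order_by_beta: bool = True,
) -> SubpatternModel:
    """Fit one FastICA sub-model per block and compute adaptive weights.

    Per-block seeds derive from ``(seed, block_index)``, so refitting with
    the same seed is bit-identical. Weights come from leave-one-out
    nearest-neighbor recognition over the training set unless an explicit
    ``weight_eval`` split is given.
    """
    shape = train.image_shape
    grid.block_shape(shape)  # validates divisibility
    labels = train.labels()
    per_block_stacks: list[np.ndarray] = []
    for b in range(grid.n_blocks):
        cols = [
            partition_blocks(s.pixels, grid)[b].reshape(-1) for s in train
        ]
        per_block_stacks.append(np.column_stack(cols))

    block_models: list[ICAModel] = []
    block_features: list[np.ndarray] = []
    for b, Xb in enumerate(per_block_stacks):
        try:
            model = fit_ica_features(
                Xb, n_components=n_components, seed=_block_seed(seed, b)
            )
        except Exception as exc:
            raise RuntimeError(f"block {b}: ICA fit failed") from exc
        feats = model.loadings(Xb)  # c x M_train, base-image loading scale
        counts: dict[str, int] = {}
        for lab in labels:
            counts[lab] = counts.get(lab, 0) + 1
        balanced = len(set(counts.values())) == 1 and min(counts.values()) >= 2
        if order_by_beta and balanced:
            table = evaluation_factors(feats.T, labels=labels)
            order = table.selected
            model.unmixing = model.unmixing[order]
            model.mixing_estimate = model.mixing_estimate[:, order]
            feats = feats[order]
        block_models.append(model)
        block_features.append(feats)

    n_comp = min(f.shape[0] for f in block_features)
    model = SubpatternModel(
        grid=grid,
        block_models=block_models,
        block_features=block_features,
        train_labels=labels,
        classes=train.classes,
        weights=np.full(grid.n_blocks, 1.0 / grid.n_blocks),
        image_shape=shape,
        n_components=n_comp,
    )
    model.weights = adaptive_weights(model, weight_eval)
    return model


def _nn_label(train_feats: np.ndarray, labels: list[str], q: np.ndarray,
              exclude: int | None = None) -> str:
    d2 = np.sum((train_feats - q[:, None]) ** 2, axis=0)
    if exclude is not None:
        d2[exclude] = np.inf
    return labels[int(np.argmin(d2))]


def adaptive_weights(
    model: SubpatternModel, eval_set: ImageDataset | None = None
) -> np.ndarray:
    """Per-block recognition rates, normalized to sum to one.

    With no explicit evaluation split, rates come from leave-one-out
    nearest neighbor over the cached training features (avoids test-set
    leakage). If every block scores zero the weights fall back to uniform.
    """
    n_blocks = model.grid.n_blocks
    rates = np.zeros(n_blocks)
    if eval_set is None:
        labels = model.train_labels
        for b in range(n_blocks):
            F = model.block_features[b]
            correct = sum(
                _nn_label(F, labels, F[:, i], exclude=i) == labels[i]
                for i in range(F.shape[1])
            )
            rates[b] = correct / F.shape[1]
    else:
        if len(eval_set) == 0:
            raise ValueError("empty evaluation set")
        for b in range(n_blocks):
            F = model.block_features[b]
            correct = 0
            for s in eval_set:
                blk = partition_blocks(s.pixels, model.grid)[b]
                q = model.block_models[b].loadings(blk.reshape(-1)[:, None])[:, 0]
                correct += _nn_label(F, model.train_labels, q) == s.label
            rates[b] = correct / len(eval_set)
    total = rates.sum()
    if total <= 0:
        return np.full(n_blocks, 1.0 / n_blocks)
    return rates / total


def classify_weighted_vote(
    model: SubpatternModel,
    sample: ImageSample | np.ndarray,
    dim: int | None = None,
) -> tuple[str, np.ndarray]:
    """Classify by weight-summed block votes.

    Each block votes for the class of its nearest training sub-block using
    the leading ``dim`` block features (all fitted components by default);
    the class score is the sum of the voting blocks' weights and the argmax
    wins, ties broken by lower class index.
    """
    feats = model._block_query_features(sample)
    scores = np.zeros(len(model.classes))
    class_index = {c: i for i, c in enumerate(model.classes)}
    for b in range(model.grid.n_blocks):
        F = model.block_features[b]
        q = feats[b]
        if dim is not None:
            F = F[:dim]
            q = q[:dim]
        vote = _nn_label(F, model.train_labels, q)
        scores[class_index[vote]] += model.weights[b]
    return model.classes[int(np.argmax(scores))], scores
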