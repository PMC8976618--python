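"""Grayscale image datasets: loading, vectorization, and seeded splits.

Datasets live on disk as ``root/<class_label>/<image files>`` with one
subdirectory per class. Images are converted to luminance, scaled to
``[0, 1]`` floats, center-cropped to the largest square and resized to a
common target size at load time, so every downstream algorithm sees
identically shaped, well-conditioned matrices.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import imageio.v3 as iio
import numpy as np
from skimage.transform import resize as _sk_resize

__all__ = [
    "ImageSample",
    "ImageDataset",
    "SplitSpec",
    "load_dataset",
    "save_dataset",
    "write_manifest",
    "vectorize",
    "devectorize",
    "random_split",
]

_IMAGE_SUFFIXES = {".png", ".tif", ".tiff", ".pgm"}


@dataclass(frozen=True)
class ImageSample:
    """A single labeled grayscale image with pixels in ``[0, 1]``."""

    pixels: np.ndarray
    label: str
    id: str

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=np.float64)
        if px.ndim != 2 or px.shape[0] < 2 or px.shape[1] < 2:
            raise ValueError(f"sample {self.id!r}: pixels must be 2-D, at least 2x2")
        if not np.all(np.isfinite(px)):
            raise ValueError(f"sample {self.id!r}: non-finite pixel values")
        if px.min() < 0.0 or px.max() > 1.0:
            raise ValueError(f"sample {self.id!r}: pixel values outside [0, 1]")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class ImageDataset:
    """An ordered collection of samples grouped into M classes."""

    samples: list[ImageSample] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.samples:
            shape = self.samples[0].shape
            for s in self.samples:
                if s.shape != shape:
                    raise ValueError(
                        f"inconsistent image shapes: {s.shape} vs {shape}"
                    )

    def __len__(self) -> int:
        return len(self.samples)

    def __iter__(self):
        return iter(self.samples)

    @property
    def classes(self) -> list[str]:
        """Distinct labels in first-appearance order."""
        seen: dict[str, None] = {}
        for s in self.samples:
            seen.setdefault(s.label, None)
        return list(seen)

    @property
    def image_shape(self) -> tuple[int, int]:
        if not self.samples:
            raise ValueError("empty dataset has no image shape")
        return self.samples[0].shape

    @property
    def images_per_class(self) -> int:
        """Per-class count N when the dataset is balanced."""
        counts = self.class_counts()
        n = set(counts.values())
        if len(n) != 1:
            raise ValueError(f"dataset is unbalanced: {counts}")
        return n.pop()

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.samples:
            counts[s.label] = counts.get(s.label, 0) + 1
        return counts

    def by_class(self, label: str) -> list[ImageSample]:
        return [s for s in self.samples if s.label == label]

    def labels(self) -> list[str]:
        return [s.label for s in self.samples]

    def to_matrix(self) -> np.ndarray:
        """Stack vectorized samples as columns: an (m*n) x M matrix."""
        if not self.samples:
            raise ValueError("empty dataset")
        return np.column_stack([vectorize(s) for s in self.samples])


@dataclass(frozen=True)
class SplitSpec:
    """P-per-class random split, reproducible from (seed, repeat_index)."""

    train_per_class: int
    seed: int
    repeat_index: int = 0

    def __post_init__(self) -> None:
        if self.train_per_class < 1:
            raise ValueError("train_per_class must be >= 1")


def vectorize(sample: ImageSample | np.ndarray) -> np.ndarray:
    """Concatenate image rows end-to-end into a length m*n vector."""
    px = sample.pixels if isinstance(sample, ImageSample) else np.asarray(sample)
    return px.reshape(-1).astype(np.float64, copy=True)


def devectorize(vector: np.ndarray, rows: int, cols: int) -> np.ndarray:
    """Inverse of :func:`vectorize`: reshape a length rows*cols vector."""
    v = np.asarray(vector, dtype=np.float64)
    if v.size != rows * cols:
        raise ValueError(f"vector length {v.size} != {rows}*{cols}")
    return v.reshape(rows, cols)


def _to_grayscale_unit(arr: np.ndarray) -> np.ndarray:
    """Convert a raw decoded image to float64 luminance in [0, 1]."""
    a = np.asarray(arr)
    if a.ndim == 3:
        if a.shape[2] == 4:
            a = a[:, :, :3]
        # ITU-R 601 luma weights
        a = a @ np.array([0.299, 0.587, 0.114])
    if np.issubdtype(np.asarray(arr).dtype, np.integer):
        info = np.iinfo(np.asarray(arr).dtype)
        a = a.astype(np.float64) / float(info.max)
    else:
        a = a.astype(np.float64)
    return np.clip(a, 0.0, 1.0)


def _center_crop_square(px: np.ndarray) -> np.ndarray:
    m, n = px.shape
    side = min(m, n)
    r0 = (m - side) // 2
    c0 = (n - side) // 2
    return px[r0 : r0 + side, c0 : c0 + side]


def preprocess_image(px: np.ndarray, target_size: tuple[int, int]) -> np.ndarray:
    """Center-crop to the largest square, then bilinear-resize to target."""
    px = _center_crop_square(px)
    if px.shape != tuple(target_size):
        px = _sk_resize(px, target_size, order=1, anti_aliasing=True)
    return np.clip(px, 0.0, 1.0)


def load_dataset(
    root_path: str | Path, target_size: tuple[int, int] | None = None
) -> ImageDataset:
    """Load a class-per-subdirectory image tree into an :class:`ImageDataset`.

    Parameters
    ----------
    root_path
        Directory containing one subdirectory per class.
    target_size
        Common (rows, cols) all images are cropped/resized to. ``None``
        keeps native sizes (they must already agree).
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset root {root} is not a directory")
    class_dirs = sorted(p for p in root.iterdir() if p.is_dir())
    if not class_dirs:
        raise ValueError(f"dataset root {root} contains no class directories")
    samples: list[ImageSample] = []
    for cdir in class_dirs:
        files = sorted(
            p for p in cdir.iterdir() if p.suffix.lower() in _IMAGE_SUFFIXES
        )
        if not files:
            raise ValueError(f"class directory {cdir.name!r} contains no images")
        for f in files:
            try:
                raw = iio.imread(f)
            except Exception as exc:  # pragma: no cover - codec specific
                raise OSError(f"cannot read image file {f}") from exc
            px = _to_grayscale_unit(raw)
            if target_size is not None:
                px = preprocess_image(px, target_size)
            samples.append(
                ImageSample(pixels=px, label=cdir.name, id=f"{cdir.name}/{f.stem}")
            )
    return ImageDataset(samples=samples)


def save_dataset(dataset: ImageDataset, root_path: str | Path) -> list[Path]:
    """Write a dataset to the ``root/<class>/`` layout as 8-bit PNGs."""
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for s in dataset:
        cdir = root / s.label
        cdir.mkdir(exist_ok=True)
        name = s.id.split("/")[-1]
        path = cdir / f"{name}.png"
        iio.imwrite(path, np.round(s.pixels * 255.0).astype(np.uint8))
        written.append(path)
    return written


def write_manifest(dataset: ImageDataset, root_path: str | Path) -> Path:
    """Write a CSV manifest (id, class, path, rows, cols) beside the images."""
    root = Path(root_path)
    path = root / "manifest.csv"
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "class", "path", "rows", "cols"])
        for s in dataset:
            name = s.id.split("/")[-1]
            writer.writerow(
                [s.id, s.label, f"{s.label}/{name}.png", s.shape[0], s.shape[1]]
            )
    return path


def _split_rng(spec: SplitSpec) -> np.random.Generator:
    # independent, reproducible stream per (seed, repeat)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(spec.repeat_index,))
    )


def random_split(
    dataset: ImageDataset, spec: SplitSpec
) -> tuple[ImageDataset, ImageDataset]:
    """Select P training images per class at random; the rest are test.

    Identical ``(seed, repeat_index)`` always produces the identical split.
    """
    rng = _split_rng(spec)
    train: list[ImageSample] = []
    test: list[ImageSample] = []
    for label in dataset.classes:
        members = dataset.by_class(label)
        if spec.train_per_class >= len(members):
            raise ValueError(
                f"class {label!r} has {len(members)} samples; cannot take "
                f"P={spec.train_per_class} for training"
            )
        idx = rng.permutation(len(members))
        chosen = set(idx[: spec.train_per_class].tolist())
        for i, s in enumerate(members):
            (train if i in chosen else test).append(s)
    return ImageDataset(samples=train), ImageDataset(samples=test)
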