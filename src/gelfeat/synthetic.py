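"""Seeded generators for gel-state image benchmarks and BSS demo signals.

Heat-set protein gels change appearance systematically with gelation
temperature and time: pore count rises sharply toward 100 °C and the gel
surface darkens with longer heating. The image generator emulates exactly
the statistical structure those experiments need — a class-dependent pore
texture (Poisson-count dark disks), a class-dependent base shade, a smooth
correlated background texture, a random linear illumination gradient as a
nuisance factor, and optional occlusion patches — without attempting
photorealism. Every generator is fully deterministic under its seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.ndimage import gaussian_filter

from gelfeat.image_io import ImageDataset, ImageSample

__all__ = [
    "GelClassSpec",
    "OcclusionSpec",
    "GenConfig",
    "default_gel_classes",
    "generate_gel_image",
    "generate_dataset",
    "apply_occlusion",
    "generate_bss_signals",
]

# fixed pore contrast: how much darker a pore center is than its surround.
# Kept shallow so that the class-dependent mean field (shade + expected pore
# coverage) dominates the placement noise of individual pores; 1-NN on
# pixel-derived features cannot classify otherwise.
_PORE_DEPTH = 0.12


@dataclass(frozen=True)
class GelClassSpec:
    """Appearance parameters of one gel state (one class)."""

    label: str
    pore_density: float  # expected pores per image
    pore_radius_range: tuple[float, float] = (1.5, 3.0)
    base_intensity: float = 0.7  # mean background level in [0, 1]
    texture_scale: float = 8.0  # correlation length (px) of background noise
    # share of pores drawn from a central cluster instead of uniformly:
    # moisture migration concentrates porosity toward the gel center as
    # gelation progresses, giving each state a spatial pore signature
    pore_concentration: float = 0.0

    def __post_init__(self) -> None:
        if self.pore_density < 0:
            raise ValueError("pore_density must be nonnegative")
        if not 0.0 <= self.pore_concentration <= 1.0:
            raise ValueError("pore_concentration must lie in [0, 1]")
        if self.pore_radius_range[0] < 1:
            raise ValueError("minimum pore radius must be >= 1 pixel")
        if not 0.0 <= self.base_intensity <= 1.0:
            raise ValueError("base_intensity must lie in [0, 1]")


@dataclass(frozen=True)
class OcclusionSpec:
    """A rectangular patch overwriting part of an image.

    ``region`` is (row0, col0, height, width) in pixels; ``fraction`` is the
    share of images the patch is applied to.
    """

    region: tuple[int, int, int, int]
    fill_value: float = 0.0
    fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if not 0.0 <= self.fill_value <= 1.0:
            raise ValueError("fill_value must lie in [0, 1]")


@dataclass(frozen=True)
class GenConfig:
    """Full recipe for a balanced synthetic gel-image dataset."""

    classes: tuple[GelClassSpec, ...]
    per_class: int = 10
    image_size: tuple[int, int] = (128, 128)
    illumination_gradient_max: float = 0.15
    occlusion: OcclusionSpec | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.per_class < 2:
            raise ValueError("per_class must be >= 2")
        if self.illumination_gradient_max < 0:
            raise ValueError("illumination amplitude must be >= 0")


def default_gel_classes(n_classes: int = 10) -> tuple[GelClassSpec, ...]:
    """The default gel-state ladder.

    Pore density rises and the base shade darkens monotonically across the
    ladder, mirroring increasing gelation temperature/time: sparse pores on
    a light gel at one end, a heavily pitted darker (browned) gel at the
    other, its porosity drawn toward the gel center by moisture migration.
    The shade ladder carries the dominant global signal; pore density and
    its growing central concentration add correlated textural and spatial
    cues.
    """
    densities = np.linspace(2.0, 48.0, n_classes)
    shades = np.linspace(0.88, 0.32, n_classes)
    concentrations = np.linspace(0.0, 0.9, n_classes)
    return tuple(
        GelClassSpec(
            label=f"state_{i:02d}",
            pore_density=float(densities[i]),
            base_intensity=float(shades[i]),
            pore_concentration=float(concentrations[i]),
        )
        for i in range(n_classes)
    )


def _textured_background(
    spec: GelClassSpec, size: tuple[int, int], rng: np.random.Generator,
    amplitude: float = 0.05,
) -> np.ndarray:
    bg = np.full(size, spec.base_intensity)
    if spec.texture_scale > 0 and amplitude > 0:
        noise = rng.standard_normal(size)
        smooth = gaussian_filter(noise, sigma=spec.texture_scale, mode="wrap")
        # remove the surviving DC component before rescaling: texture is
        # zero-mean local variation; global brightness offsets belong to
        # the illumination nuisance, not the gel surface
        smooth -= smooth.mean()
        sd = smooth.std()
        if sd > 0:
            bg = bg + smooth * (amplitude / sd)
    return bg


def _stamp_pores(
    img: np.ndarray, spec: GelClassSpec, rng: np.random.Generator
) -> None:
    m, n = img.shape
    count = rng.poisson(spec.pore_density)
    rr, cc = np.mgrid[0:m, 0:n]
    lo, hi = spec.pore_radius_range
    for _ in range(count):
        if rng.uniform() < spec.pore_concentration:
            # central cluster, truncated to the frame
            cy = np.clip(rng.normal(m / 2, 0.18 * m), 0, m - 1)
            cx = np.clip(rng.normal(n / 2, 0.18 * n), 0, n - 1)
        else:
            cy, cx = rng.uniform(0, m), rng.uniform(0, n)
        radius = rng.uniform(lo, hi)
        # soft-edged disk: ~1 inside, smooth 1-px falloff at the rim
        dist = np.sqrt((rr - cy) ** 2 + (cc - cx) ** 2)
        mask = np.clip(radius + 0.5 - dist, 0.0, 1.0)
        img -= _PORE_DEPTH * mask


def _illumination_plane(
    size: tuple[int, int], amplitude_max: float, rng: np.random.Generator
) -> np.ndarray:
    m, n = size
    if amplitude_max <= 0:
        return np.zeros(size)
    # direction fully random; strength always substantial so that lighting
    # is a real nuisance for every image, never a no-op
    theta = rng.uniform(0, 2 * np.pi)
    amp = rng.uniform(0.5 * amplitude_max, amplitude_max)
    rows = np.linspace(-0.5, 0.5, m)[:, None]
    cols = np.linspace(-0.5, 0.5, n)[None, :]
    return amp * (np.cos(theta) * rows + np.sin(theta) * cols) * 2.0


def generate_gel_image(
    spec: GelClassSpec,
    size: tuple[int, int] = (128, 128),
    seed: int | np.random.SeedSequence = 0,
    illumination_gradient_max: float = 0.0,
    sample_id: str | None = None,
) -> ImageSample:
    """Generate one gel-state image: textured background, Poisson-count
    dark pores, and an additive linear illumination gradient, clipped to
    [0, 1]."""
    rng = np.random.default_rng(seed)
    img = _textured_background(spec, size, rng)
    _stamp_pores(img, spec, rng)
    img += _illumination_plane(size, illumination_gradient_max, rng)
    return ImageSample(
        pixels=np.clip(img, 0.0, 1.0),
        label=spec.label,
        id=sample_id or f"{spec.label}/img_0",
    )


def apply_occlusion(
    dataset: ImageDataset, occ: OcclusionSpec, seed: int = 0
) -> ImageDataset:
    """Overwrite the occlusion region in a seeded fraction of the images."""
    rng = np.random.default_rng(seed)
    r0, c0, h, w = occ.region
    out = []
    for s in dataset:
        if rng.uniform() < occ.fraction:
            px = s.pixels.copy()
            px[r0 : r0 + h, c0 : c0 + w] = occ.fill_value
            out.append(ImageSample(pixels=px, label=s.label, id=s.id))
        else:
            out.append(s)
    return ImageDataset(samples=out)


def generate_dataset(config: GenConfig) -> ImageDataset:
    """Generate a balanced M-class x N-image dataset per the config."""
    samples = []
    for ci, spec in enumerate(config.classes):
        for ni in range(config.per_class):
            ss = np.random.SeedSequence(
                entropy=config.seed, spawn_key=(ci, ni)
            )
            samples.append(
                generate_gel_image(
                    spec,
                    size=config.image_size,
                    seed=ss,
                    illumination_gradient_max=config.illumination_gradient_max,
                    sample_id=f"{spec.label}/img_{ni:03d}",
                )
            )
    ds = ImageDataset(samples=samples)
    if config.occlusion is not None:
        ds = apply_occlusion(ds, config.occlusion, seed=config.seed)
    return ds


def generate_bss_signals(n_samples: int = 2000, seed: int = 0) -> np.ndarray:
    """Four canonical independent sources for blind source separation.

    Returns a 4 x n matrix: sine, square and sawtooth waves at mutually
    incommensurate frequencies plus uniform white noise, each standardized
    to zero mean, unit variance. Random phases keep the deterministic waves
    decorrelated across seeds.
    """
    if n_samples < 512:
        raise ValueError("n_samples must be >= 512")
    rng = np.random.default_rng(seed)
    t = np.arange(n_samples, dtype=np.float64)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    # irrational-ratio frequencies (cycles per sample)
    f_sin, f_sq, f_saw = 0.017, 0.017 * np.sqrt(2), 0.017 * np.sqrt(5)
    sources = np.vstack(
        [
            np.sin(2 * np.pi * f_sin * t + phases[0]),
            _signal.square(2 * np.pi * f_sq * t + phases[1]),
            _signal.sawtooth(2 * np.pi * f_saw * t + phases[2]),
            rng.uniform(-1.0, 1.0, size=n_samples),
        ]
    )
    sources -= sources.mean(axis=1, keepdims=True)
    sources /= sources.std(axis=1, keepdims=True)
    return sources
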