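"""One-level 2-D discrete wavelet decomposition and the Wavelet-PCA pipeline.

A single separable DWT level splits an image into four subbands: the
low-frequency approximation LL (a smooth, roughly half-size version of the
image) and the horizontal / vertical / diagonal detail bands HL, LH, HH.
Wavelet-PCA replaces each raw image with its LL subband before PCA, which
shrinks the vectorized dimension about fourfold while keeping the gross
structure the eigen decomposition feeds on.

The transform itself delegates to PyWavelets; this module pins the package's
conventions (Daubechies family, db2 default, periodization boundary so
subbands are exactly half-size and energy is conserved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from gelfeat.image_io import ImageDataset, ImageSample
from gelfeat.pca import FeatureVector, PCAModel, fit_pca, project

__all__ = [
    "SUPPORTED_WAVELETS",
    "WaveletDecomposition",
    "dwt2",
    "idwt2",
    "WaveletPCAModel",
    "fit_wavelet_pca",
    "subband_images",
]

SUPPORTED_WAVELETS = tuple(f"db{i}" for i in range(1, 9))
_SUPPORTED_MODES = ("periodization", "symmetric")


@dataclass(frozen=True)
class WaveletDecomposition:
    """The four subbands of a one-level separable 2-D DWT."""

    LL: np.ndarray
    HL: np.ndarray
    LH: np.ndarray
    HH: np.ndarray
    wavelet_name: str = "db2"
    level: int = 1
    boundary_mode: str = "periodization"

    def __post_init__(self) -> None:
        shapes = {self.LL.shape, self.HL.shape, self.LH.shape, self.HH.shape}
        if len(shapes) != 1:
            raise ValueError(f"subband shapes differ: {shapes}")


def _check_config(wavelet_name: str, boundary_mode: str) -> None:
    if wavelet_name not in SUPPORTED_WAVELETS:
        raise ValueError(
            f"unknown wavelet {wavelet_name!r}; supported: {SUPPORTED_WAVELETS}"
        )
    if boundary_mode not in _SUPPORTED_MODES:
        raise ValueError(
            f"unknown boundary mode {boundary_mode!r}; supported: {_SUPPORTED_MODES}"
        )


def dwt2(
    image: np.ndarray,
    wavelet_name: str = "db2",
    boundary_mode: str = "periodization",
) -> WaveletDecomposition:
    """One-level separable 2-D analysis: filter rows and columns, downsample.

    With periodization the subbands of an (2r, 2c) image are exactly (r, c).
    """
    _check_config(wavelet_name, boundary_mode)
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError("image must be 2-D")
    flen = pywt.Wavelet(wavelet_name).dec_len
    if min(img.shape) < flen:
        raise ValueError(f"image dims {img.shape} below filter length {flen}")
    cA, (cH, cV, cD) = pywt.dwt2(img, wavelet_name, mode=boundary_mode)
    return WaveletDecomposition(
        LL=cA,
        HL=cH,
        LH=cV,
        HH=cD,
        wavelet_name=wavelet_name,
        boundary_mode=boundary_mode,
    )


def idwt2(decomp: WaveletDecomposition) -> np.ndarray:
    """Synthesis reconstruction; exact inverse for orthonormal wavelets."""
    _check_config(decomp.wavelet_name, decomp.boundary_mode)
    return pywt.idwt2(
        (decomp.LL, (decomp.HL, decomp.LH, decomp.HH)),
        decomp.wavelet_name,
        mode=decomp.boundary_mode,
    )


def subband_images(decomp: WaveletDecomposition) -> dict[str, np.ndarray]:
    """Each subband affinely rescaled to [0, 1] for visual inspection."""
    out = {}
    for name in ("LL", "HL", "LH", "HH"):
        band = getattr(decomp, name)
        lo, hi = band.min(), band.max()
        out[name] = (band - lo) / (hi - lo) if hi > lo else np.zeros_like(band)
    return out


@dataclass
class WaveletPCAModel:
    """PCA fitted on LL subbands; projection runs DWT first."""

    pca: PCAModel
    wavelet_name: str
    boundary_mode: str
    original_shape: tuple[int, int]

    @property
    def retained(self) -> int:
        return self.pca.retained

    @property
    def eigenvalues(self) -> np.ndarray:
        return self.pca.eigenvalues


def _ll_sample(
    sample: ImageSample, wavelet_name: str, boundary_mode: str
) -> ImageSample:
    ll = dwt2(sample.pixels, wavelet_name, boundary_mode).LL
    # Raw coefficients passed to PCA up to one FIXED affine map shared by all
    # images (needed only to satisfy the [0,1] sample invariant). A common
    # shift is absorbed by PCA centering and a common scale changes nothing
    # but the eigenvalue units. LL of a [0,1] image under orthonormal dbN
    # lies well inside [-1, 3] (two cascaded low-pass gains of sqrt(2)).
    return ImageSample(
        pixels=np.clip((ll + 1.0) / 4.0, 0.0, 1.0), label=sample.label, id=sample.id
    )


def fit_wavelet_pca(
    train: ImageDataset,
    p: int | None = None,
    wavelet_name: str = "db2",
    boundary_mode: str = "periodization",
) -> WaveletPCAModel:
    """Fit PCA on the LL subbands of the training images."""
    _check_config(wavelet_name, boundary_mode)
    ll_train = ImageDataset(
        samples=[_ll_sample(s, wavelet_name, boundary_mode) for s in train]
    )
    orig_dim = int(np.prod(train.image_shape))
    ll_dim = int(np.prod(ll_train.image_shape))
    if ll_dim >= orig_dim:
        raise ValueError(
            f"LL dimension {ll_dim} not smaller than original {orig_dim}"
        )
    return WaveletPCAModel(
        pca=fit_pca(ll_train, p),
        wavelet_name=wavelet_name,
        boundary_mode=boundary_mode,
        original_shape=train.image_shape,
    )


def project_wavelet(model: WaveletPCAModel, sample: ImageSample) -> FeatureVector:
    """Compute the LL subband of a sample, then its PCA projection."""
    if sample.shape != model.original_shape:
        raise ValueError(
            f"sample shape {sample.shape} != model shape {model.original_shape}"
        )
    ll = _ll_sample(sample, model.wavelet_name, model.boundary_mode)
    fv = project(model.pca, ll)
    return FeatureVector(values=fv.values, model_id="wavelet_pca")
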