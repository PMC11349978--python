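"""Wavelet fusion of the two enhanced knee views.

Each enhanced view is reduced to its luminance plane, decomposed by a
one-level Daubechies-4 2-D DWT (symmetric boundary extension), and the
subbands are combined with maximum-eigenvalue weighting: the largest
singular value of each approximation subband yields a common approximation
gain (Max-Ei), the largest singular value over the six detail subbands a
common detail gain (Max-Elow).  All subbands are scaled by their band's
gain, the corresponding scaled subbands of the two views are summed, and
the inverse DWT reconstructs the fused image.

Because both views share the same per-band gain, the raw combination is a
two-gain amplifier of the bandwise sums.  The final rescale step therefore
(i) normalises each fused band by its common gain — restoring the spectral
balance of the inputs, so fusing an image with itself reproduces it exactly
— and (ii) affinely maps the reconstruction onto ``value_range``.  The
literal un-normalised subbands and reconstruction remain available through
:class:`FusionIntermediates` for inspection.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt

from .image import DEFAULT_RANGE, rescale_to_range

__all__ = [
    "SubbandSet",
    "FusionIntermediates",
    "to_luminance",
    "dwt_decompose",
    "dwt_reconstruct",
    "max_eigen",
    "fuse_images",
]

_WAVELET = "db4"
_MODE = "symmetric"


@dataclass
class SubbandSet:
    """One-level 2-D DWT decomposition: approximation + H/V/D details."""

    A: np.ndarray
    H: np.ndarray
    V: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        shapes = {self.A.shape, self.H.shape, self.V.shape, self.D.shape}
        if len(shapes) != 1:
            raise ValueError(f"subbands must share one shape, got {shapes}")


@dataclass
class FusionIntermediates:
    """Literal per-equation intermediates of the fusion rule."""

    max_ei: float
    max_elow: float
    scaled1: SubbandSet  # view-1 subbands after gain scaling
    scaled2: SubbandSet  # view-2 subbands after gain scaling
    summed: SubbandSet  # elementwise sum of the scaled subband pairs
    literal_fused: np.ndarray  # inverse DWT of `summed`, before any rescale
    prenorm_fused: np.ndarray  # gain-normalised reconstruction, before the affine rescale


def to_luminance(image: np.ndarray) -> np.ndarray:
    """Luminance plane of a grayscale (identity) or RGB image.

    RGB uses the full-range BT.601 luma weights, so pure white maps to 255.
    """
    arr = np.asarray(image, dtype=float)
    if arr.ndim == 2:
        return arr
    if arr.ndim == 3 and arr.shape[2] == 3:
        return 0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
    raise ValueError(f"expected 1 or 3 channels, got shape {arr.shape}")


def dwt_decompose(image: np.ndarray) -> SubbandSet:
    """One-level db4 decomposition with symmetric extension."""
    arr = np.asarray(image, dtype=float)
    filt_len = pywt.Wavelet(_WAVELET).dec_len
    if min(arr.shape) < filt_len:
        raise ValueError(
            f"image dimensions {arr.shape} are smaller than the db4 support ({filt_len})"
        )
    A, (H, V, D) = pywt.dwt2(arr, _WAVELET, mode=_MODE)
    return SubbandSet(A, H, V, D)


def dwt_reconstruct(subbands: SubbandSet, shape: tuple[int, int] | None = None) -> np.ndarray:
    """Inverse of :func:`dwt_decompose`; optionally cropped to ``shape``."""
    rec = pywt.idwt2((subbands.A, (subbands.H, subbands.V, subbands.D)), _WAVELET, mode=_MODE)
    if shape is not None:
        rec = rec[: shape[0], : shape[1]]
    return rec


def max_eigen(subband: np.ndarray) -> float:
    """Largest singular value of a (possibly rectangular) subband.

    Singular values are the square roots of the eigenvalues of the
    subband's Gram matrix, which extends the eigenvalue notion to
    non-square matrices; the result is always non-negative.
    """
    arr = np.asarray(subband, dtype=float)
    if arr.size == 0:
        raise ValueError("subband is empty")
    return float(np.linalg.svd(arr, compute_uv=False)[0])


def fuse_images(
    enh1: np.ndarray,
    enh2: np.ndarray,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    return_intermediates: bool = False,
):
    """Fuse two enhanced views of the same knee into one image.

    Returns the fused image (same shape as the inputs, spanning
    ``value_range``); with ``return_intermediates=True`` also returns the
    :class:`FusionIntermediates` holding every literal step.
    """
    y1 = to_luminance(enh1)
    y2 = to_luminance(enh2)
    if y1.shape != y2.shape:
        raise ValueError(f"view shapes differ: {y1.shape} vs {y2.shape}")
    sb1 = dwt_decompose(y1)
    sb2 = dwt_decompose(y2)

    max_ei = max(max_eigen(sb1.A), max_eigen(sb2.A))
    max_elow = max(
        max_eigen(sb1.H), max_eigen(sb1.V), max_eigen(sb1.D),
        max_eigen(sb2.H), max_eigen(sb2.V), max_eigen(sb2.D),
    )

    def scale(sb: SubbandSet) -> SubbandSet:
        return SubbandSet(sb.A * max_ei, sb.H * max_elow, sb.V * max_elow, sb.D * max_elow)

    s1, s2 = scale(sb1), scale(sb2)
    summed = SubbandSet(s1.A + s2.A, s1.H + s2.H, s1.V + s2.V, s1.D + s2.D)
    literal = dwt_reconstruct(summed, y1.shape)

    # per-band gain normalisation: divide each fused band by its common
    # gain (and the factor 2 from summing both views) so the fused image
    # keeps the inputs' spectral balance; fuse(x, x) is then exactly x
    a_div = 2.0 * max_ei if max_ei > 0 else 1.0
    d_div = 2.0 * max_elow if max_elow > 0 else 1.0
    normalised = SubbandSet(summed.A / a_div, summed.H / d_div, summed.V / d_div, summed.D / d_div)
    prenorm = dwt_reconstruct(normalised, y1.shape)
    fused = rescale_to_range(prenorm, value_range)

    if return_intermediates:
        return fused, FusionIntermediates(max_ei, max_elow, s1, s2, summed, literal, prenorm)
    return fused
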