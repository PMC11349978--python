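"""Adaptive Local Histogram Equalization (ALHE) for low-contrast radiographs.

The image is split into small non-overlapping tiles; within each tile the
intensity histogram and its cumulative distribution (CDF, normalised by the
tile's pixel count) are computed, and every pixel is multiplied by the CDF
value of its own intensity bin.  Pixels at the top occupied bin of a tile
keep their value (CDF = 1); darker pixels are attenuated in proportion to
how much of the tile lies at or below them, which steepens local contrast
while preserving edges.
"""

from __future__ import annotations

import numpy as np

from .image import DEFAULT_RANGE, as_gray, rescale_to_range

__all__ = ["alhe_enhance"]


def _bin_indices(image, value_range, n_bins):
    lo, hi = value_range
    idx = np.floor((image - lo) / (hi - lo) * n_bins).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def alhe_enhance(
    image: np.ndarray,
    region_size: int = 5,
    n_bins: int = 256,
    value_range: tuple[float, float] = DEFAULT_RANGE,
    rescale: bool = True,
) -> np.ndarray:
    """Enhance ``image`` by per-tile CDF weighting.

    Parameters
    ----------
    image : ndarray
        2-D grayscale raster with intensities in ``value_range``.
    region_size : int
        Tile edge length in pixels.  When a dimension is not divisible by
        ``region_size`` the edge tiles are smaller partial tiles processed
        with their own histograms.
    n_bins : int
        Histogram bins spanning ``value_range`` (floor binning).
    rescale : bool
        The raw CDF product shrinks intensities; when True (default) the
        result is linearly rescaled per image to span ``value_range`` so
        downstream binarisation stays stable.  Pass False for the raw
        product.

    Returns
    -------
    ndarray of the same shape as ``image``.
    """
    arr = as_gray(image)
    if region_size < 1:
        raise ValueError("region_size must be >= 1")
    h, w = arr.shape
    if region_size > h and region_size > w:
        raise ValueError(
            f"region_size {region_size} exceeds both image dimensions {arr.shape}"
        )
    bins = _bin_indices(arr, value_range, n_bins)
    out = np.empty_like(arr)
    for r0 in range(0, h, region_size):
        r1 = min(r0 + region_size, h)
        for c0 in range(0, w, region_size):
            c1 = min(c0 + region_size, w)
            tile_bins = bins[r0:r1, c0:c1]
            counts = np.bincount(tile_bins.ravel(), minlength=n_bins)
            cdf = np.cumsum(counts) / tile_bins.size
            out[r0:r1, c0:c1] = arr[r0:r1, c0:c1] * cdf[tile_bins]
    if rescale:
        out = rescale_to_range(out, value_range)
    return out
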