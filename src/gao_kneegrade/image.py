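"""Grayscale image helpers shared across the pipeline.

Images are plain 2-D float numpy arrays carrying intensities inside an
explicit ``value_range`` (default 8-bit, ``(0, 255)``).  Keeping the raster a
bare ndarray lets every stage interoperate with numpy/scipy/skimage without
wrapper friction.
"""

from __future__ import annotations

import numpy as np

DEFAULT_RANGE = (0.0, 255.0)


def as_gray(image: np.ndarray) -> np.ndarray:
    """Validate and return a 2-D float64 view of ``image``."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ValueError("image must have positive height and width")
    return arr


def rescale_to_range(
    image: np.ndarray, value_range: tuple[float, float] = DEFAULT_RANGE
) -> np.ndarray:
    """Affinely map an image onto ``value_range``.

    Constant images are returned unchanged (clipped into range) so the map
    is idempotent on them instead of collapsing to the lower bound.
    """
    lo, hi = value_range
    arr = np.asarray(image, dtype=float)
    mn, mx = float(arr.min()), float(arr.max())
    if mx == mn:
        return np.clip(arr, lo, hi)
    return lo + (arr - mn) * (hi - lo) / (mx - mn)


def read_gray(path) -> np.ndarray:
    """Read an 8/16-bit PNG or TIFF as a float grayscale array."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        # luminance of an RGB(A) file, full-range BT.601 weights
        arr = (
            0.299 * arr[..., 0] + 0.587 * arr[..., 1] + 0.114 * arr[..., 2]
        )
    return arr.astype(float)


def write_gray(path, image: np.ndarray, value_range=DEFAULT_RANGE) -> None:
    """Write a grayscale image as 8-bit PNG/TIFF (clipped into range)."""
    import imageio.v3 as iio

    lo, hi = value_range
    arr = np.clip(np.asarray(image, dtype=float), lo, hi)
    scaled = (arr - lo) / (hi - lo) * 255.0
    iio.imwrite(path, scaled.round().astype(np.uint8))
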