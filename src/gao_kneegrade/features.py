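"""Morphological features of the segmented joint region.

Six features summarise the region: the mean, Pearson kurtosis (normal -> 3)
and skewness of the masked intensities, plus the eccentricity and the
major/minor axis lengths of the region's equivalent ellipse (from the
central second moments of the mask, with a +1/12 per-pixel variance
correction so a single pixel has well-defined axes).  Tiling these features
over the image yields the Morphological Feature Matrix (MFM), the 6-channel
spatial map consumed by the second CNN branch.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
from scipy import stats

__all__ = [
    "IntensityStats",
    "ShapeMoments",
    "MorphFeatureMatrix",
    "intensity_stats",
    "shape_moments",
    "morph_feature_vector",
    "build_mfm",
    "FEATURE_NAMES",
]

FEATURE_NAMES = ("mean", "kurtosis", "skewness", "eccentricity", "major_axis", "minor_axis")


class IntensityStats(NamedTuple):
    mean: float
    kurtosis: float
    skewness: float
    degenerate: bool  # True when the masked intensities have zero variance


class ShapeMoments(NamedTuple):
    eccentricity: float
    major_axis_length: float
    minor_axis_length: float


def intensity_stats(image: np.ndarray, mask: np.ndarray) -> IntensityStats:
    """Mean, Pearson kurtosis (m4/m2^2) and skewness (m3/m2^1.5) of masked pixels.

    Zero-variance regions get kurtosis = skewness = 0 with the
    ``degenerate`` flag set.
    """
    values = np.asarray(image, dtype=float)[np.asarray(mask).astype(bool)]
    if values.size == 0:
        raise ValueError("mask selects no pixels")
    mean = float(values.mean())
    if values.size == 1 or float(values.var()) == 0.0:
        return IntensityStats(mean, 0.0, 0.0, True)
    kurt = float(stats.kurtosis(values, fisher=False, bias=True))
    skew = float(stats.skew(values, bias=True))
    return IntensityStats(mean, kurt, skew, False)


def shape_moments(mask: np.ndarray) -> ShapeMoments:
    """Equivalent-ellipse axes and eccentricity of a binary region.

    The axes are 4*sqrt of the eigenvalues of the pixel-coordinate
    covariance (central second moments normalised by area), with 1/12
    added to each diagonal term for the variance of a unit pixel; a filled
    disc of radius R then has both axes ~2R, and a single pixel has equal
    axes and eccentricity 0.
    """
    coords = np.argwhere(np.asarray(mask).astype(bool))
    if coords.shape[0] == 0:
        raise ValueError("mask is empty")
    centred = coords - coords.mean(axis=0)
    cov = centred.T @ centred / coords.shape[0] + np.eye(2) / 12.0
    eigvals = np.linalg.eigvalsh(cov)  # ascending
    minor = 4.0 * math.sqrt(float(eigvals[0]))
    major = 4.0 * math.sqrt(float(eigvals[1]))
    ecc = math.sqrt(max(0.0, 1.0 - eigvals[0] / eigvals[1]))
    return ShapeMoments(ecc, major, minor)


def morph_feature_vector(image: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """The 6-vector (mean, kurtosis, skewness, ecc, major, minor) of a region."""
    ist = intensity_stats(image, mask)
    sm = shape_moments(mask)
    return np.array(
        [ist.mean, ist.kurtosis, ist.skewness, sm.eccentricity, sm.major_axis_length, sm.minor_axis_length]
    )


@dataclass
class MorphFeatureMatrix:
    """Per-tile 6-channel morphological feature map."""

    grid: np.ndarray  # (rows, cols, 6)
    tile_size: int
    occupied: np.ndarray  # (rows, cols) bool: tile intersects the mask

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.grid.shape[:2]


def build_mfm(
    image: np.ndarray,
    mask: np.ndarray,
    tile_size: int = 16,
    standardize: bool = True,
) -> MorphFeatureMatrix:
    """Tile the image and compute the 6 features over (tile & mask) per tile.

    Tiles with no masked pixels get a zero vector.  With ``standardize``
    (default) each channel is shifted/scaled to zero mean and unit variance
    over the occupied tiles, which keeps the second CNN branch's input
    scale stable across images.
    """
    if tile_size < 4:
        raise ValueError("tile_size must be >= 4")
    img = np.asarray(image, dtype=float)
    msk = np.asarray(mask).astype(bool)
    if img.shape != msk.shape:
        raise ValueError("image and mask shapes differ")
    rows = -(-img.shape[0] // tile_size)
    cols = -(-img.shape[1] // tile_size)
    grid = np.zeros((rows, cols, 6))
    occupied = np.zeros((rows, cols), dtype=bool)
    for r in range(rows):
        for c in range(cols):
            sl = (
                slice(r * tile_size, min((r + 1) * tile_size, img.shape[0])),
                slice(c * tile_size, min((c + 1) * tile_size, img.shape[1])),
            )
            sub_mask = msk[sl]
            if not sub_mask.any():
                continue
            occupied[r, c] = True
            grid[r, c] = morph_feature_vector(img[sl], sub_mask)
    if standardize and occupied.any():
        occ = grid[occupied]
        mean = occ.mean(axis=0)
        std = occ.std(axis=0)
        std[std == 0] = 1.0
        grid[occupied] = (occ - mean) / std
    return MorphFeatureMatrix(grid, tile_size, occupied)
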