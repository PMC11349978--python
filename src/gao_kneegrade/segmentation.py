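"""Knee-joint localisation in the fused radiograph.

The fused image is binarised (Otsu threshold), cleaned with a 3x3 binary
majority filter, and labelled into connected components.  The default
joint rule treats the bright bone as foreground and takes the joint space
to be the per-column band between the two largest bone components — its
anatomical definition; the alternative rule binarises the dark gap
directly and selects the largest component whose centroid falls in the
central horizontal band of the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

__all__ = [
    "RegionMask",
    "binarize",
    "majority_filter_3x3",
    "connected_components",
    "select_joint_region",
    "between_bones_region",
    "segment_knee_joint",
]


@dataclass
class RegionMask:
    """A selected region: binary mask, tight half-open bbox, pixel area."""

    mask: np.ndarray
    bounding_box: tuple[int, int, int, int]  # (row0, col0, row1, col1), half-open
    area: int
    fallback: bool = False  # True when no component met the central-band rule


def binarize(image: np.ndarray, foreground: str = "dark") -> np.ndarray:
    """Otsu-threshold binarisation.

    ``foreground="dark"`` maps pixels below the threshold to 1 (the
    radiographic joint space is dark); ``"bright"`` inverts the polarity.
    A constant image yields an all-zero mask with a warning.
    """
    arr = np.asarray(image, dtype=float)
    if foreground not in ("dark", "bright"):
        raise ValueError("foreground must be 'dark' or 'bright'")
    if arr.min() == arr.max():
        warnings.warn("constant image: binarization yields an empty mask", stacklevel=2)
        return np.zeros(arr.shape, dtype=np.uint8)
    t = threshold_otsu(arr)
    mask = arr < t if foreground == "dark" else arr > t
    return mask.astype(np.uint8)


def majority_filter_3x3(binary: np.ndarray) -> np.ndarray:
    """Per-pixel majority vote over the 3x3 neighbourhood (binary median).

    Edges are handled by replication, so every vote is over 9 samples and
    ties cannot occur.
    """
    arr = np.asarray(binary)
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError("image must be at least 3x3")
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("input must be binary (0/1)")
    counts = ndimage.correlate(arr.astype(np.int32), np.ones((3, 3), dtype=np.int32), mode="nearest")
    return (counts >= 5).astype(np.uint8)


def connected_components(binary: np.ndarray, connectivity: int = 8) -> tuple[np.ndarray, int]:
    """Label foreground components (8-connected by default).

    Returns (labels, n_components); labels are contiguous positive
    integers, background is 0.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    labels, n = cc_label(np.asarray(binary), connectivity=1 if connectivity == 4 else 2, return_num=True)
    return labels, n


def _region_from_mask(mask: np.ndarray, fallback: bool) -> RegionMask:
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        return RegionMask(mask.astype(np.uint8), (0, 0, 0, 0), 0, fallback)
    bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
    return RegionMask(mask.astype(np.uint8), bbox, int(rows.size), fallback)


def select_joint_region(
    labels: np.ndarray,
    central_band: tuple[float, float] = (0.25, 0.75),
) -> RegionMask:
    """Pick the joint component: largest area with centroid in the central rows.

    Components whose row centroid lies within ``central_band`` (fractions of
    the image height) compete by area, ties going to the lower label.  If no
    component reaches the band the globally largest one is returned with the
    ``fallback`` flag set.
    """
    labels = np.asarray(labels)
    n = int(labels.max())
    if n < 1:
        raise ValueError("no components to select from")
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    centroids = ndimage.center_of_mass(np.ones_like(labels), labels, idx)
    lo = central_band[0] * labels.shape[0]
    hi = central_band[1] * labels.shape[0]
    central = [i for i, c in zip(idx, centroids) if lo <= c[0] < hi]
    if central:
        # np.argmax over areas keeps the first (lowest-label) maximum
        pick = central[int(np.argmax([areas[i - 1] for i in central]))]
        fallback = False
    else:
        pick = int(idx[int(np.argmax(areas))])
        fallback = True
    return _region_from_mask(labels == pick, fallback)


def between_bones_region(labels: np.ndarray, n: int) -> RegionMask | None:
    """Joint space as the per-column band between the two largest components.

    The two largest labelled components are taken as femur and tibia
    (ordered by row centroid); the region is, column by column, the strip
    strictly between the lower edge of the upper bone and the upper edge
    of the lower bone.  Returns None when fewer than two components exist
    or the bones do not face each other anywhere.
    """
    if n < 2:
        return None
    idx = np.arange(1, n + 1)
    areas = ndimage.sum_labels(np.ones_like(labels), labels, idx)
    top2 = idx[np.argsort(areas)[-2:]]
    cents = ndimage.center_of_mass(np.ones_like(labels), labels, top2)
    if cents[0][0] <= cents[1][0]:
        upper_mask, lower_mask = labels == top2[0], labels == top2[1]
    else:
        upper_mask, lower_mask = labels == top2[1], labels == top2[0]
    region = np.zeros(labels.shape, dtype=np.uint8)
    for c in range(labels.shape[1]):
        ur = np.nonzero(upper_mask[:, c])[0]
        lr = np.nonzero(lower_mask[:, c])[0]
        if ur.size and lr.size and ur.max() < lr.min():
            region[ur.max() + 1 : lr.min(), c] = 1
    if not region.any():
        return None
    return _region_from_mask(region, fallback=False)


def segment_knee_joint(
    fused: np.ndarray,
    method: str = "between_bones",
    connectivity: int = 8,
    central_band: tuple[float, float] = (0.25, 0.75),
) -> RegionMask:
    """Locate the joint-space region of a fused knee image.

    ``method="between_bones"`` (default) binarises with the bright bone as
    foreground, majority-filters, labels, and takes the band between the
    two largest bone components — the anatomical definition of the joint
    space, robust to dark speckle that survives filtering.
    ``method="central_dark"`` binarises with the dark gap as foreground and
    selects the largest component whose centroid lies in the central rows.
    Either way the chain is binarise -> majority filter -> label -> select.
    """
    if method not in ("between_bones", "central_dark"):
        raise ValueError("method must be 'between_bones' or 'central_dark'")
    polarity = "bright" if method == "between_bones" else "dark"
    binary = binarize(fused, foreground=polarity)
    if binary.any():
        binary = majority_filter_3x3(binary)
    if not binary.any():
        warnings.warn("no foreground found; returning an empty region", stacklevel=2)
        return _region_from_mask(np.zeros_like(binary), fallback=True)
    labels, n = connected_components(binary, connectivity=connectivity)
    if method == "between_bones":
        region = between_bones_region(labels, n)
        if region is not None:
            return region
        # fall back to the dark-component rule when two bones are not found
        dark = binarize(fused, foreground="dark")
        if dark.any():
            dark = majority_filter_3x3(dark)
        if not dark.any():
            warnings.warn("no joint-space candidate found; empty region", stacklevel=2)
            return _region_from_mask(np.zeros_like(binary), fallback=True)
        labels, n = connected_components(dark, connectivity=connectivity)
    return select_joint_region(labels, central_band=central_band)
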