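"""Segmentation comparison metrics (Dice overlap, boundary Hausdorff)."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["dice", "boundary_hausdorff", "interior_mask_of", "zero_level_radius"]


def interior_mask_of(ls, image_shape=None) -> np.ndarray:
    """Foreground mask (phi <= 0) of a level set, optionally embedded in a
    full image-domain array."""
    mask = ls.interior_mask()
    if image_shape is None:
        return mask
    full = np.zeros(image_shape, dtype=bool)
    full[ls.region.slices()] = mask
    return full


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A.B| / (|A| + |B|); 1.0 for two empty masks."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * float(np.logical_and(a, b).sum()) / float(denom)


def _boundary(mask: np.ndarray) -> np.ndarray:
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    return mask & ~ndimage.binary_erosion(mask, structure=structure, border_value=0)


def boundary_hausdorff(a: np.ndarray, b: np.ndarray) -> float:
    """Symmetric Hausdorff distance (px) between the boundaries of two
    masks, computed from Euclidean distance transforms."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    ba, bb = _boundary(a), _boundary(b)
    if not ba.any() or not bb.any():
        return 0.0 if ba.any() == bb.any() else float("inf")
    d_to_b = ndimage.distance_transform_edt(~bb)
    d_to_a = ndimage.distance_transform_edt(~ba)
    return float(max(d_to_b[ba].max(), d_to_a[bb].max()))


def zero_level_radius(ls, center=None) -> float:
    """Mean distance of the zero level-curve from a center (2D dense).

    Vertices come from sub-pixel marching squares on the value field.
    """
    from skimage import measure

    values = ls.values
    if center is None:
        center = tuple((s - 1) / 2.0 + o for s, o in zip(ls.region.shape, ls.region.offset))
    contours = measure.find_contours(values, 0.0)
    if not contours:
        return float("nan")
    local_center = tuple(c - o for c, o in zip(center, ls.region.offset))
    radii = []
    for contour in contours:
        d = np.sqrt(((contour - np.array(local_center)) ** 2).sum(axis=1))
        radii.extend(d.tolist())
    return float(np.mean(radii))
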