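"""Adaptors between binary masks and level-set representations.

The dense adaptor turns a binary mask into a signed-distance field whose
zero crossing sits midway between boundary pixel pairs:
``phi = -(EDT_bg - 0.5)`` on foreground, ``+(EDT_fg - 0.5)`` on background,
with the Euclidean distance transform measured to the nearest pixel of the
opposite class.  The sparse adaptors build the layer structure directly
from 4-/6-connected adjacency, with integer initial layer values.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import ndimage

from .errors import DegenerateInputError
from .grids import DenseLevelSet, GridRegion
from .sparse import SparseLevelSet

__all__ = [
    "binary_to_dense",
    "binary_to_sparse",
    "sparse_to_dense",
    "mask_from_seed",
]


def _check_mask(mask: np.ndarray):
    mask = np.asarray(mask, dtype=bool)
    if mask.all() or not mask.any():
        raise DegenerateInputError(
            "mask must contain at least one foreground and one background pixel"
        )
    return mask


def binary_to_dense(mask, region: GridRegion = None, spacing=None) -> DenseLevelSet:
    """Signed-distance level set (inside-negative) from a binary mask."""
    mask = _check_mask(mask)
    if region is None:
        region = GridRegion((0,) * mask.ndim, mask.shape)
    sampling = spacing if spacing is not None else 1.0
    d_bg = ndimage.distance_transform_edt(mask, sampling=sampling)  # fg -> nearest bg
    d_fg = ndimage.distance_transform_edt(~mask, sampling=sampling)  # bg -> nearest fg
    phi = np.where(mask, -(d_bg - 0.5), d_fg - 0.5)
    return DenseLevelSet(region, phi, spacing=spacing)


def _boundary(mask: np.ndarray, structure) -> np.ndarray:
    """Foreground pixels with at least one background 4-/6-neighbor."""
    return mask & ~ndimage.binary_erosion(mask, structure=structure, border_value=1)


def _touches_border(mask: np.ndarray) -> bool:
    return any(
        mask.take(0, axis=ax).any() or mask.take(-1, axis=ax).any()
        for ax in range(mask.ndim)
    )


def binary_to_sparse(mask, variant: str, region: GridRegion = None,
                     image_domain: GridRegion = None, spacing=None,
                     erode_border: bool = True) -> SparseLevelSet:
    """Narrow-band level set from a binary mask.

    Masks touching the region border are eroded by one pixel (with a
    warning) so the inside layers never touch the border; pass
    ``erode_border=False`` to keep the mask as-is (stencils fall back to
    one-sided differences there).
    """
    mask = _check_mask(mask)
    if region is None:
        region = GridRegion((0,) * mask.ndim, mask.shape)
    structure = ndimage.generate_binary_structure(mask.ndim, 1)
    if erode_border and _touches_border(mask):
        eroded = ndimage.binary_erosion(mask, structure=structure, border_value=0)
        if eroded.any():
            warnings.warn(
                "mask touches the region border; eroding by 1 px before building layers",
                stacklevel=2,
            )
            mask = eroded
        else:
            warnings.warn(
                "mask touches the region border and cannot be eroded; "
                "layers will touch the border",
                stacklevel=2,
            )

    ls = SparseLevelSet(variant, region, image_domain=image_domain, spacing=spacing)
    interior, exterior = ls.interior_sentinel, ls.exterior_sentinel

    fg_boundary = _boundary(mask, structure)
    bg_boundary = ~mask & ndimage.binary_dilation(mask, structure=structure)

    def assign(layer_mask: np.ndarray, layer: int, value: float):
        for local in zip(*np.nonzero(layer_mask)):
            ls.set_layer(tuple(int(v) for v in region.to_global(local)), layer, value)

    if variant == "whitaker":
        l0 = fg_boundary
        lm1 = mask & ~l0 & ndimage.binary_dilation(l0, structure=structure)
        lm2 = mask & ~l0 & ~lm1 & ndimage.binary_dilation(lm1, structure=structure)
        lp1 = bg_boundary
        lp2 = ~mask & ~lp1 & ndimage.binary_dilation(lp1, structure=structure)
        ls.values[:] = float(exterior)
        ls.values[mask] = float(interior)
        ls.label[:] = exterior
        ls.label[mask] = interior
        for layer_mask, layer in ((l0, 0), (lm1, -1), (lm2, -2), (lp1, 1), (lp2, 2)):
            assign(layer_mask, layer, float(layer))
    elif variant == "shi":
        ls.values[:] = float(exterior)
        ls.values[mask] = float(interior)
        ls.label[:] = exterior
        ls.label[mask] = interior
        assign(fg_boundary, -1, -1.0)
        assign(bg_boundary, 1, 1.0)
    else:  # malcolm
        ls.values[:] = float(exterior)
        ls.values[mask] = float(interior)
        ls.label[:] = exterior
        ls.label[mask] = interior
        assign(fg_boundary, 0, 0.0)
    return ls


def sparse_to_dense(ls: SparseLevelSet) -> DenseLevelSet:
    """Dense field carrying layer values in-band and sentinels off-band."""
    return DenseLevelSet(ls.region, ls.values.copy(), spacing=ls.spacing)


def mask_from_seed(center, radius: float, shape) -> np.ndarray:
    """Binary sphere/disk mask: pixels within ``radius`` of ``center``."""
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return r2 <= radius**2
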