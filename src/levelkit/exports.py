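"""Static visualization exports: contours, elevation maps, layer maps.

Contours are extracted with marching squares (2D, sub-pixel CSV polygons)
or marching cubes (3D, OBJ mesh).  The elevation export color-maps the
value field of a 2D dense level set; the layer export paints each sparse
layer id in a fixed color.
"""

from __future__ import annotations

import csv
import warnings
from pathlib import Path

import numpy as np
from matplotlib import colormaps

from .errors import ConfigurationError
from .grids import DenseLevelSet
from .io import write_image
from .sparse import SparseLevelSet, layer_ids

__all__ = ["export_contours", "export_elevation", "export_layers", "LAYER_COLORS"]

CONTOUR_HEADER = ["contour_id", "vertex_order", "y", "x"]

#: Fixed RGB color per sparse layer id (background stays neutral gray).
LAYER_COLORS = {
    -2: (0, 0, 180),
    -1: (0, 120, 255),
    0: (255, 255, 0),
    1: (255, 140, 0),
    2: (200, 0, 0),
}
_BACKGROUND_COLOR = (64, 64, 64)


def _dense_values(ls):
    if isinstance(ls, SparseLevelSet):
        from .adaptors import sparse_to_dense

        ls = sparse_to_dense(ls)
    return ls


def export_contours(ls, path, isovalue: float = 0.0):
    """Write the zero level as sub-pixel polygons (2D CSV) or a mesh (3D OBJ).

    Vertex coordinates are global (region offset applied).  Without a zero
    crossing an empty file with the header is written, with a warning.
    """
    from skimage import measure

    ls = _dense_values(ls)
    values = ls.values
    path = Path(path)
    if values.ndim == 2:
        contours = measure.find_contours(values, isovalue)
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CONTOUR_HEADER)
            for cid, contour in enumerate(contours):
                for order, (y, x) in enumerate(contour):
                    writer.writerow(
                        [cid, order, y + ls.region.offset[0], x + ls.region.offset[1]]
                    )
        if not contours:
            warnings.warn(f"no zero crossing; wrote empty contour file {path}", stacklevel=2)
        return len(contours)
    if values.ndim == 3:
        if values.min() > isovalue or values.max() < isovalue:
            with open(path, "w") as fh:
                fh.write("# empty mesh: no zero crossing\n")
            warnings.warn(f"no zero crossing; wrote empty mesh {path}", stacklevel=2)
            return 0
        verts, faces, _, _ = measure.marching_cubes(values, isovalue)
        verts = verts + np.array(ls.region.offset)
        with open(path, "w") as fh:
            for v in verts:
                fh.write(f"v {v[0]:.6f} {v[1]:.6f} {v[2]:.6f}\n")
            for f in faces:
                fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
        return 1
    raise ConfigurationError("contour export supports 2D and 3D level sets only")


def export_elevation(ls, path, cmap: str = "viridis"):
    """Color-mapped height image (PNG) of a 2D dense level set."""
    if not isinstance(ls, DenseLevelSet):
        raise ConfigurationError("elevation export requires a dense level set")
    values = ls.values
    if values.ndim != 2:
        raise ConfigurationError("elevation export is 2D only")
    lo, hi = float(values.min()), float(values.max())
    normalized = np.zeros_like(values) if hi == lo else (values - lo) / (hi - lo)
    rgba = colormaps[cmap](normalized)
    rgb = (rgba[..., :3] * 255).astype(np.uint8)
    _write_rgb_png(rgb, path)


def export_layers(ls, path):
    """PNG with one fixed color per sparse layer id, neutral background."""
    if not isinstance(ls, SparseLevelSet):
        raise ConfigurationError("layer export requires a sparse level set")
    if ls.label.ndim != 2:
        raise ConfigurationError("layer export is 2D only")
    rgb = np.empty(ls.label.shape + (3,), dtype=np.uint8)
    rgb[...] = _BACKGROUND_COLOR
    for k in layer_ids(ls.variant):
        rgb[ls.label == k] = LAYER_COLORS[k]
    _write_rgb_png(rgb, path)


def _write_rgb_png(rgb, path):
    import imageio.v3 as iio

    path = Path(path)
    if path.suffix.lower() != ".png":
        raise ConfigurationError(f"expected a .png path, got {path}")
    iio.imwrite(path, rgb)


def write_label_field(ls, path):
    """Sparse label field as signed 8-bit TIFF (or dense sign field)."""
    if isinstance(ls, SparseLevelSet):
        write_image(ls.label.astype(np.int8), path)
    else:
        write_image(np.sign(ls.values).astype(np.int8), path)
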