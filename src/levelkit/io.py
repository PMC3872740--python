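"""Image reading and writing (grayscale PNG and TIFF).

PNG covers 2D 8/16-bit integer images; TIFF covers 2D and 3D stacks of
8/16-bit integers or 32-bit floats (axis order (z, y, x)).  Intensities
are cast to float for processing; writing preserves the array dtype, so a
32-bit float TIFF round-trips bit-exactly.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .errors import LevelSetError

__all__ = ["read_image", "write_image"]

_PNG_DTYPES = (np.uint8, np.uint16)
_TIFF_DTYPES = (np.uint8, np.uint16, np.int8, np.int16, np.float32)


class ImageIOError(LevelSetError):
    pass


def read_image(path) -> np.ndarray:
    """Read a grayscale PNG/TIFF into a float array."""
    path = Path(path)
    if not path.exists():
        raise ImageIOError(f"no such image file: {path}")
    suffix = path.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            data = tifffile.imread(path)
        elif suffix == ".png":
            data = iio.imread(path)
        else:
            raise ImageIOError(f"unsupported image format {suffix!r} for {path}")
    except ImageIOError:
        raise
    except Exception as exc:
        raise ImageIOError(f"failed to read {path}: {exc}") from exc
    if data.ndim == 3 and suffix == ".png":
        raise ImageIOError(f"{path}: color PNG not supported (grayscale only)")
    return np.asarray(data, dtype=float)


def write_image(field, path):
    """Write an array as PNG (2D integer) or TIFF (any supported dtype).

    Float arrays destined for TIFF are stored as 32-bit float; float
    arrays cannot be written to PNG.
    """
    path = Path(path)
    field = np.asarray(field)
    suffix = path.suffix.lower()
    if suffix == ".png":
        if field.dtype not in _PNG_DTYPES:
            raise ImageIOError(
                f"PNG supports uint8/uint16, got {field.dtype} for {path}"
            )
        iio.imwrite(path, field)
    elif suffix in (".tif", ".tiff"):
        if np.issubdtype(field.dtype, np.floating):
            field = field.astype(np.float32)
        elif field.dtype not in _TIFF_DTYPES:
            field = field.astype(np.int16)
        tifffile.imwrite(path, field)
    else:
        raise ImageIOError(f"unsupported image format {suffix!r} for {path}")
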