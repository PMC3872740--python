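"""Grid-backed level-set functions and cached derivative queries.

A level-set function ``phi`` is sampled on an integer pixel grid over a
rectangular region of the image domain.  The zero level-curve of ``phi`` is
the object boundary; ``phi < 0`` strictly inside the object
(*inside-negative* convention).  Axis order is (row, col) in 2D and
(z, y, x) in 3D; indices are 0-based and regions are half-open
``[offset, offset + shape)``.

All derivative queries use central finite differences and fall back to
one-sided differences on the region border.  A :class:`QuantityCache` bound
to one evaluation point guarantees each quantity is computed at most once
per point, however many PDE terms request it.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, DomainError

__all__ = [
    "GridRegion",
    "DenseLevelSet",
    "QuantityCache",
    "QUANTITIES",
    "evaluate_cached",
]

#: Quantity names recognised by :class:`QuantityCache`.
QUANTITIES = (
    "value",
    "gradient",
    "hessian",
    "laplacian",
    "gradient_norm",
    "mean_curvature",
    "forward_gradient",
    "backward_gradient",
)

#: Below this gradient norm the mean curvature is defined as 0.
CURVATURE_GRADIENT_TOL = 1e-8


@dataclass(frozen=True)
class GridRegion:
    """Axis-aligned half-open box ``[offset, offset + shape)`` on the pixel grid."""

    offset: tuple
    shape: tuple

    def __post_init__(self):
        offset = tuple(int(o) for o in self.offset)
        shape = tuple(int(s) for s in self.shape)
        if len(offset) != len(shape):
            raise ConfigurationError("offset and shape must have equal length")
        if any(s <= 0 for s in shape):
            raise ConfigurationError(f"region shape must be strictly positive, got {shape}")
        object.__setattr__(self, "offset", offset)
        object.__setattr__(self, "shape", shape)

    @property
    def ndim(self) -> int:
        return len(self.shape)

    @property
    def stop(self) -> tuple:
        return tuple(o + s for o, s in zip(self.offset, self.shape))

    def contains(self, idx) -> bool:
        return all(o <= i < o + s for i, o, s in zip(idx, self.offset, self.shape))

    def contains_region(self, other: "GridRegion") -> bool:
        return all(
            so >= o and so + ss <= o + s
            for so, ss, o, s in zip(other.offset, other.shape, self.offset, self.shape)
        )

    def to_local(self, idx) -> tuple:
        return tuple(i - o for i, o in zip(idx, self.offset))

    def to_global(self, local) -> tuple:
        return tuple(i + o for i, o in zip(local, self.offset))

    def slices(self) -> tuple:
        """Slices addressing this region inside an image-domain-sized array."""
        return tuple(slice(o, o + s) for o, s in zip(self.offset, self.shape))

    def indices(self):
        """Iterate all global indices in raster-scan order."""
        for local in np.ndindex(*self.shape):
            yield self.to_global(local)

    @property
    def centroid(self) -> tuple:
        return tuple(o + (s - 1) / 2.0 for o, s in zip(self.offset, self.shape))

    @property
    def half_diagonal(self) -> float:
        return 0.5 * math.sqrt(sum((s - 1) ** 2 for s in self.shape))


class _StencilMixin:
    """Finite-difference derivative queries shared by dense and sparse grids.

    Subclasses provide ``self.values`` (array over ``self.region``),
    ``self.region`` and ``self.spacing``.  ``self.eval_counts`` counts how
    often each stencil is actually evaluated (cache-soundness
    instrumentation).
    """

    def _local(self, idx) -> tuple:
        if not self.region.contains(idx):
            raise DomainError(f"index {idx} outside region {self.region}")
        return self.region.to_local(idx)

    # -- first derivatives ------------------------------------------------

    def _d1(self, local, axis, mode="central") -> float:
        v = self.values
        n = v.shape[axis]
        h = self.spacing[axis]
        i = local[axis]
        lo = list(local)
        hi = list(local)
        if mode == "central":
            if 0 < i < n - 1:
                lo[axis] -= 1
                hi[axis] += 1
                return float(v[tuple(hi)] - v[tuple(lo)]) / (2.0 * h)
            mode = "forward" if i == 0 else "backward"
        if mode == "forward":
            if i == n - 1:  # border fallback
                mode = "backward"
            else:
                hi[axis] += 1
                return float(v[tuple(hi)] - v[tuple(local)]) / h
        # backward
        if i == 0:
            hi[axis] += 1
            return float(v[tuple(hi)] - v[tuple(local)]) / h
        lo[axis] -= 1
        return float(v[tuple(local)] - v[tuple(lo)]) / h

    def _d2(self, local, axis) -> float:
        v = self.values
        n = v.shape[axis]
        h = self.spacing[axis]
        i = min(max(local[axis], 1), n - 2)  # shift stencil inward at borders
        lo = list(local)
        md = list(local)
        hi = list(local)
        lo[axis], md[axis], hi[axis] = i - 1, i, i + 1
        return float(v[tuple(hi)] - 2.0 * v[tuple(md)] + v[tuple(lo)]) / (h * h)

    def _dxy(self, local, ax_a, ax_b) -> float:
        v = self.values
        ha, hb = self.spacing[ax_a], self.spacing[ax_b]
        na, nb = v.shape[ax_a], v.shape[ax_b]
        ia = min(max(local[ax_a], 1), na - 2)
        ib = min(max(local[ax_b], 1), nb - 2)
        total = 0.0
        for sa in (-1, 1):
            for sb in (-1, 1):
                p = list(local)
                p[ax_a] = ia + sa
                p[ax_b] = ib + sb
                total += sa * sb * float(v[tuple(p)])
        return total / (4.0 * ha * hb)

    # -- public queries ---------------------------------------------------

    def value(self, idx) -> float:
        self.eval_counts["value"] += 1
        return float(self.values[self._local(idx)])

    def gradient(self, idx) -> np.ndarray:
        self.eval_counts["gradient"] += 1
        local = self._local(idx)
        return np.array([self._d1(local, ax) for ax in range(self.region.ndim)])

    def forward_gradient(self, idx) -> np.ndarray:
        self.eval_counts["forward_gradient"] += 1
        local = self._local(idx)
        return np.array(
            [self._d1(local, ax, "forward") for ax in range(self.region.ndim)]
        )

    def backward_gradient(self, idx) -> np.ndarray:
        self.eval_counts["backward_gradient"] += 1
        local = self._local(idx)
        return np.array(
            [self._d1(local, ax, "backward") for ax in range(self.region.ndim)]
        )

    def hessian(self, idx) -> np.ndarray:
        self.eval_counts["hessian"] += 1
        local = self._local(idx)
        d = self.region.ndim
        H = np.empty((d, d))
        for a in range(d):
            H[a, a] = self._d2(local, a)
            for b in range(a + 1, d):
                H[a, b] = H[b, a] = self._dxy(local, a, b)
        return H

    def laplacian(self, idx) -> float:
        self.eval_counts["laplacian"] += 1
        local = self._local(idx)
        return sum(self._d2(local, ax) for ax in range(self.region.ndim))

    def gradient_norm(self, idx) -> float:
        self.eval_counts["gradient_norm"] += 1
        local = self._local(idx)
        return math.sqrt(
            sum(self._d1(local, ax) ** 2 for ax in range(self.region.ndim))
        )

    def mean_curvature(self, idx) -> float:
        """div(grad phi / |grad phi|) by central differences; 0 where the
        gradient is degenerate (|grad phi| < 1e-8)."""
        self.eval_counts["mean_curvature"] += 1
        local = self._local(idx)
        d = self.region.ndim
        g = np.array([self._d1(local, ax) for ax in range(d)])
        gnorm2 = float(g @ g)
        if gnorm2 < CURVATURE_GRADIENT_TOL**2:
            return 0.0
        H = np.empty((d, d))
        for a in range(d):
            H[a, a] = self._d2(local, a)
            for b in range(a + 1, d):
                H[a, b] = H[b, a] = self._dxy(local, a, b)
        return float((np.trace(H) * gnorm2 - g @ H @ g) / gnorm2**1.5)


class DenseLevelSet(_StencilMixin):
    """Level-set function stored as a full scalar field over its region.

    Parameters
    ----------
    region : GridRegion
        Placement of the field inside the image domain.
    values : ndarray
        Signed values (pixel units) of shape ``region.shape``.
    spacing : sequence of float, optional
        Physical pixel size per axis (default 1 everywhere).
    """

    representation = "dense"

    def __init__(self, region: GridRegion, values, spacing=None):
        values = np.asarray(values, dtype=float)
        if tuple(values.shape) != tuple(region.shape):
            raise ConfigurationError(
                f"values shape {values.shape} != region shape {region.shape}"
            )
        if not np.all(np.isfinite(values)):
            raise ConfigurationError("level-set values must be finite")
        self.region = region
        self.values = values
        self.spacing = (
            tuple(float(s) for s in spacing) if spacing is not None else (1.0,) * region.ndim
        )
        if len(self.spacing) != region.ndim:
            raise ConfigurationError("spacing must have one entry per axis")
        self.eval_counts = Counter()

    def copy(self) -> "DenseLevelSet":
        return DenseLevelSet(self.region, self.values.copy(), self.spacing)

    def interior_mask(self) -> np.ndarray:
        """Boolean foreground mask (phi <= 0) over the region."""
        return self.values <= 0.0


@dataclass
class QuantityCache:
    """Compute-once store of level-set quantities at a single grid point.

    Shared by all terms of one equation while evaluating one pixel; cleared
    (or replaced) when moving to the next pixel.  Entries keep a
    computed-flag so instrumentation can verify nothing is evaluated twice.
    """

    ls: object
    idx: tuple
    _entries: dict = field(default_factory=dict)

    def get(self, name: str):
        if name not in QUANTITIES:
            raise ConfigurationError(f"unknown level-set quantity {name!r}")
        if name in self._entries:
            return self._entries[name]
        value = getattr(self.ls, name)(self.idx)
        self._entries[name] = value
        return value

    def computed(self, name: str) -> bool:
        return name in self._entries

    def clear(self):
        self._entries.clear()

    def rebind(self, idx):
        """Move the cache to a new evaluation point (clears all entries)."""
        self.idx = tuple(idx)
        self.clear()


def evaluate_cached(ls, idx, cache: QuantityCache, name: str):
    """Fetch a named quantity of ``ls`` at ``idx`` through ``cache``.

    The first request computes and flags the entry; later requests at the
    same point return the stored value without re-running the stencil.
    """
    if cache.ls is not ls or tuple(cache.idx) != tuple(idx):
        cache.ls = ls
        cache.rebind(idx)
    return cache.get(name)
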