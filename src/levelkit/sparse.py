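"""Sparse-field (narrow-band) level-set representations.

Three classic narrow-band schemes are supported, differing in how many
layers of pixels around the zero level-curve carry explicit values:

* ``whitaker`` — 5 layers with ids -2..+2; layer ``k`` values live in the
  half-open band ``[k - 0.5, k + 0.5)``; off-band pixels hold the interior
  (-3) / exterior (+3) sentinels.
* ``shi`` — 2 layers: -1 (inside boundary pixels, value -1) and +1 (outside
  boundary pixels, value +1); sentinels -3 / +3.
* ``malcolm`` — a single layer 0 on the inside boundary pixels (value 0);
  sentinels -1 / +1.

Each layer is a map from grid index to value; a signed label field over the
region mirrors the layer membership.  Off-band value queries return the
sentinel, so derivative stencils keep working through the shared
:class:`~levelkit.grids._StencilMixin` interface.
"""

from __future__ import annotations

from collections import Counter

import numpy as np

from .errors import ConfigurationError, DomainError
from .grids import GridRegion, _StencilMixin

__all__ = ["SparseLevelSet", "VARIANTS", "layer_ids", "sentinels"]

VARIANTS = ("whitaker", "shi", "malcolm")

_LAYER_IDS = {
    "whitaker": (-2, -1, 0, 1, 2),
    "shi": (-1, 1),
    "malcolm": (0,),
}
_SENTINELS = {
    "whitaker": (-3, 3),
    "shi": (-3, 3),
    "malcolm": (-1, 1),
}


def layer_ids(variant: str) -> tuple:
    return _LAYER_IDS[variant]


def sentinels(variant: str) -> tuple:
    """(interior, exterior) sentinel values for a variant."""
    return _SENTINELS[variant]


def _neighbors(idx):
    """City-block (4-/6-connectivity) neighbors of a grid index."""
    for ax in range(len(idx)):
        for step in (-1, 1):
            n = list(idx)
            n[ax] += step
            yield tuple(n)


class SparseLevelSet(_StencilMixin):
    """Layered narrow-band level-set function.

    Layers are dictionaries keyed by *global* grid index; ``label`` and
    ``values`` are arrays over the region kept consistent with the layers
    (off-band pixels hold sentinel labels/values).  The image domain, when
    registered, bounds which indices are legal to query at all.
    """

    def __init__(self, variant: str, region: GridRegion, image_domain: GridRegion = None,
                 spacing=None):
        if variant not in VARIANTS:
            raise ConfigurationError(f"unknown sparse variant {variant!r}")
        self.variant = variant
        self.representation = variant
        self.region = region
        self.image_domain = image_domain
        self.spacing = (
            tuple(float(s) for s in spacing) if spacing is not None else (1.0,) * region.ndim
        )
        interior, exterior = sentinels(variant)
        self.interior_sentinel = interior
        self.exterior_sentinel = exterior
        self.layers = {k: {} for k in layer_ids(variant)}
        self.label = np.full(region.shape, exterior, dtype=np.int8)
        self.values = np.full(region.shape, float(exterior), dtype=float)
        self.eval_counts = Counter()

    # -- value queries ----------------------------------------------------

    def value(self, idx) -> float:
        """Layer value at ``idx``; sentinel off-band or outside the region."""
        self.eval_counts["value"] += 1
        if not self.region.contains(idx):
            if self.image_domain is not None and not self.image_domain.contains(idx):
                raise DomainError(f"index {idx} outside image domain")
            return float(self.exterior_sentinel)
        return float(self.values[self.region.to_local(idx)])

    # -- band bookkeeping -------------------------------------------------

    def set_layer(self, idx, layer: int, value: float):
        """Place ``idx`` in ``layer`` with ``value``, removing it from any
        previous layer."""
        local = self.region.to_local(idx)
        old = int(self.label[local])
        if old in self.layers:
            self.layers[old].pop(idx, None)
        self.layers[layer][idx] = float(value)
        self.label[local] = layer
        self.values[local] = float(value)

    def set_value(self, idx, value: float):
        local = self.region.to_local(idx)
        layer = int(self.label[local])
        if layer not in self.layers:
            raise DomainError(f"index {idx} is not in-band")
        self.layers[layer][idx] = float(value)
        self.values[local] = float(value)

    def to_sentinel(self, idx, side: int):
        """Remove ``idx`` from the band to the interior (side<0) or exterior
        (side>0) sentinel."""
        local = self.region.to_local(idx)
        old = int(self.label[local])
        if old in self.layers:
            self.layers[old].pop(idx, None)
        s = self.interior_sentinel if side < 0 else self.exterior_sentinel
        self.label[local] = s
        self.values[local] = float(s)

    def layer_of(self, idx) -> int:
        return int(self.label[self.region.to_local(idx)])

    def band_indices(self):
        for k in layer_ids(self.variant):
            yield from self.layers[k]

    def interface_indices(self):
        """Pixels whose PDE update is computed (the zero-crossing layers)."""
        if self.variant == "shi":
            return sorted(list(self.layers[-1]) + list(self.layers[1]))
        return sorted(self.layers[0])

    def interior_mask(self) -> np.ndarray:
        """Boolean foreground mask over the region (phi <= 0)."""
        return self.values <= 0.0

    # -- consistency ------------------------------------------------------

    def check_invariants(self):
        """Assert layer/label/value consistency; raises AssertionError."""
        ids = layer_ids(self.variant)
        assert set(self.layers) == set(ids)
        seen = {}
        for k in ids:
            for idx, v in self.layers[k].items():
                assert idx not in seen, f"{idx} in layers {seen[idx]} and {k}"
                seen[idx] = k
                local = self.region.to_local(idx)
                assert int(self.label[local]) == k
                assert self.values[local] == v
                if self.variant == "whitaker":
                    assert k - 0.5 <= v < k + 0.5, f"layer {k} value {v} at {idx}"
        # every in-band label has a layer entry, sentinels have none
        for local in np.ndindex(*self.region.shape):
            lab = int(self.label[local])
            idx = self.region.to_global(local)
            if lab in self.layers:
                assert idx in self.layers[lab]
            else:
                assert lab in (self.interior_sentinel, self.exterior_sentinel)
        # band connectivity: layer k (|k|>=1) touches layer k - sign(k)
        for k in ids:
            if k == 0:
                continue
            inner = k - (1 if k > 0 else -1)
            if inner not in self.layers:
                continue
            for idx in self.layers[k]:
                ok = any(
                    self.region.contains(n) and int(self.label[self.region.to_local(n)]) == inner
                    for n in _neighbors(idx)
                )
                assert ok, f"layer {k} pixel {idx} has no layer-{inner} neighbor"
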