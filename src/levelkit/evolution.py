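"""The level-set iteration engine.

One iteration computes per-pixel updates for every level set over the
domain-map subregions (dense: every pixel of the level set's region;
sparse: the zero-crossing layer only), chooses a stable time step from the
CFL bound, applies the representation-specific update rule, refreshes term
parameters, optionally reinitializes, fires the iteration event and
consults the stopping criterion.

Update rules:

* dense — explicit Euler ``phi += dt * update``.
* whitaker — zero-layer values move by ``dt * update`` (capped at 0.5 px
  per step so layers cannot be skipped); values leaving ``[-0.5, 0.5)``
  migrate the pixel outward/inward and the surrounding layers are relaxed
  to stay unit-spaced, promoting/demoting pixels between the five bands
  and the sentinels.
* shi / malcolm — sign-driven single-pixel moves per iteration; the time
  step is ignored.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from types import MappingProxyType

import numpy as np

from .containers import EquationContainer, LevelSetContainer
from .domains import DomainPartition, build_domain_map, populate_id_lists
from .errors import ConfigurationError, NumericalError
from .events import IterationEvent, ObserverRegistry
from .grids import DenseLevelSet, GridRegion, QuantityCache
from .reinit import ReinitPolicy, apply_policy
from .sparse import SparseLevelSet, _neighbors
from .terms import _ChanVeseComponent, dirac_eps, heaviside_eps

__all__ = [
    "EvolutionState",
    "LevelSetSystem",
    "LevelSetEvolution",
    "compute_time_step",
    "update_dense",
    "update_whitaker",
    "update_shi",
    "update_malcolm",
]

DEFAULT_C_CFL = 0.45
DEFAULT_DT_MAX = 1.0
DEFAULT_HARD_CAP = 10_000
WHITAKER_MAX_STEP = 0.5  # max |delta phi| per iteration (no layer skipping)


@dataclass(frozen=True)
class EvolutionState:
    """Per-iteration convergence diagnostics."""

    iteration: int
    dt: float
    rms_change: float
    total_energy: float = None
    per_level_set: MappingProxyType = None


class LevelSetSystem:
    """Assembled image + level sets + equations + domain partition."""

    def __init__(self, image, level_sets: LevelSetContainer,
                 equations: EquationContainer, partition: DomainPartition = None):
        self.image = np.asarray(image, dtype=float)
        self.image_domain = GridRegion((0,) * self.image.ndim, self.image.shape)
        self.level_sets = level_sets
        self.equations = equations
        if set(level_sets.ids()) != set(equations.ids()):
            raise ConfigurationError(
                "level-set container ids and equation container ids differ"
            )
        if partition is None:
            partition = DomainPartition(
                self.image_domain,
                {ls_id: ls.region for ls_id, ls in level_sets.items()},
            )
        self.partition = partition
        self.param_epoch = 0
        self.domain_map = None
        self.rebuild_domain_map()
        level_sets.domain_map = self.domain_map
        equations.bind(self)

    def rebuild_domain_map(self):
        self.domain_map = build_domain_map(populate_id_lists(self.partition))
        self.level_sets.domain_map = self.domain_map

    def add_level_set(self, ls_id, ls, term_container, region: GridRegion = None):
        """Seed a new level set mid-run (between iterations)."""
        self.level_sets.add_level_set(ls_id, ls)
        self.equations.add_equation(ls_id, term_container)
        term_container.bind(self)
        term_container.initialize_parameters(self)
        self.partition.add_region(ls_id, region if region is not None else ls.region)
        self.rebuild_domain_map()

    def remove_level_set(self, ls_id):
        """Terminate a level set mid-run."""
        self.level_sets.remove_level_set(ls_id)
        self.equations.remove_equation(ls_id)
        self.partition.remove_region(ls_id)
        self.rebuild_domain_map()


# ---------------------------------------------------------------------------
# updates and time step
# ---------------------------------------------------------------------------

def compute_updates(system: LevelSetSystem) -> dict:
    """Raw d(phi)/dt buffers per level set.

    Dense buffers are arrays over the level set's region filled by walking
    the domain-map subregions (each pixel knows its active ids, so no
    per-pixel membership tests).  Sparse buffers map interface indices to
    updates.  Every pixel gets a fresh cache shared by all terms of that
    equation, and the result is independent of subregion visitation
    order (each (id, pixel) pair is evaluated exactly once).
    """
    buffers = {}
    dense = system.level_sets.representation == "dense"
    if dense:
        for ls_id, ls in system.level_sets.items():
            buffers[ls_id] = np.zeros(ls.region.shape)
        for _, ids, pixels in system.domain_map.iter_subdomains():
            active = [i for i in ids if i in system.level_sets]
            for pix in pixels:
                idx = tuple(int(v) for v in pix)
                for ls_id in active:
                    ls = system.level_sets.get_level_set(ls_id)
                    cache = QuantityCache(ls, idx)
                    buffers[ls_id][ls.region.to_local(idx)] = (
                        system.equations.get_equation(ls_id).evaluate(idx, cache)
                    )
    else:
        for ls_id, ls in system.level_sets.items():
            eq = system.equations.get_equation(ls_id)
            buf = {}
            for idx in ls.interface_indices():
                cache = QuantityCache(ls, idx)
                buf[idx] = eq.evaluate(idx, cache)
            buffers[ls_id] = buf
    return buffers


def _max_abs_update(buffers) -> float:
    peak = 0.0
    for buf in buffers.values():
        if isinstance(buf, dict):
            if buf:
                peak = max(peak, max(abs(v) for v in buf.values()))
        elif buf.size:
            peak = max(peak, float(np.max(np.abs(buf))))
    return peak


def compute_time_step(buffers, representation: str = "dense",
                      c_cfl: float = DEFAULT_C_CFL, dt_max: float = DEFAULT_DT_MAX) -> float:
    """CFL-limited time step ``c_cfl / max|update|`` clamped to ``dt_max``.

    The Whitaker band additionally forbids layer skipping
    (``dt * max|update| <= 0.5``); Shi/Malcolm moves are sign-driven and
    ignore dt (returned as 1).
    """
    if representation in ("shi", "malcolm"):
        return 1.0
    peak = _max_abs_update(buffers)
    if peak == 0.0:
        return dt_max
    c = min(c_cfl, WHITAKER_MAX_STEP) if representation == "whitaker" else c_cfl
    return min(c / (peak + 1e-12), dt_max)


def _check_finite(buffers, iteration):
    for ls_id, buf in buffers.items():
        vals = np.array(list(buf.values())) if isinstance(buf, dict) else buf
        if vals.size and not np.all(np.isfinite(vals)):
            raise NumericalError(
                f"non-finite update for level set {ls_id!r} at iteration {iteration}"
            )


def update_dense(ls: DenseLevelSet, buffer: np.ndarray, dt: float) -> float:
    """``phi += dt * buffer``; returns the RMS change over the region."""
    delta = dt * buffer
    ls.values += delta
    if not np.all(np.isfinite(ls.values)):
        raise NumericalError("non-finite level-set values after dense update")
    return float(np.sqrt(np.mean(delta**2))) if delta.size else 0.0


def _bin_whitaker(v: float) -> int:
    """Layer id whose half-open band [k-0.5, k+0.5) holds v; +-3 off-band."""
    if v < -2.5:
        return -3
    if v >= 2.5:
        return 3
    return int(math.floor(v + 0.5))


_WHITAKER_REFERENCE = {1: (0,), -1: (0,), 2: (0, 1), -2: (0, -1)}


def update_whitaker(ls: SparseLevelSet, buffer: dict, dt: float, notify=None) -> float:
    """Sparse-field update: move the zero layer, then relax the bands.

    Zero-layer values advance by ``dt * update`` and keep their membership
    while the surrounding layers are relaxed in the order +1, -1, +2, -2:
    each pixel takes (min over reference-layer neighbors + 1) on the
    positive side (max - 1 on the negative side), re-binning into
    whichever band the value lands in — this is what promotes fresh
    pixels into the zero layer as the front moves — and pixels with no
    reference neighbor are demoted outward.  Zero-layer values that left
    ``[-0.5, 0.5)`` then migrate to the +-1 layer, and the band is
    extended where it borders a sentinel.  ``notify`` receives
    (idx, old, new) for every value change.
    """

    def set_layer(idx, layer, value):
        old = ls.values[ls.region.to_local(idx)]
        ls.set_layer(idx, layer, value)
        if notify is not None and old != value:
            notify(idx, float(old), float(value))

    def to_sentinel(idx, side):
        old = ls.values[ls.region.to_local(idx)]
        ls.to_sentinel(idx, side)
        new = ls.values[ls.region.to_local(idx)]
        if notify is not None and old != new:
            notify(idx, float(old), float(new))

    # phase 1: advance the zero layer (membership unchanged for now, so
    # the relax passes see the updated front positions)
    sq_sum = 0.0
    n_zero = 0
    for idx in sorted(ls.layers[0]):
        u = buffer.get(idx, 0.0)
        old = ls.layers[0][idx]
        new = old + dt * u
        if not np.isfinite(new):
            raise NumericalError(f"non-finite zero-layer value at {idx}")
        sq_sum += (new - old) ** 2
        n_zero += 1
        ls.set_value(idx, new)
        if notify is not None and new != old:
            notify(idx, float(old), float(new))
    rms = math.sqrt(sq_sum / n_zero) if n_zero else 0.0

    # phase 2: relax the surrounding bands against the updated zero layer
    for k in (1, -1, 2, -2):
        reference = _WHITAKER_REFERENCE[k]
        for idx in sorted(ls.layers[k]):
            if ls.layer_of(idx) != k:  # moved already during this pass
                continue
            vals = []
            for n in _neighbors(idx):
                if ls.region.contains(n) and ls.layer_of(n) in reference:
                    vals.append(ls.values[ls.region.to_local(n)])
            if not vals:
                target = k + (1 if k > 0 else -1)
                if abs(target) == 3:
                    to_sentinel(idx, target)
                else:
                    set_layer(idx, target, float(target))
                continue
            v = (min(vals) + 1.0) if k > 0 else (max(vals) - 1.0)
            new_k = _bin_whitaker(v)
            if abs(new_k) == 3:
                to_sentinel(idx, new_k)
            else:
                set_layer(idx, new_k, v)

    # phase 3: migrate zero-layer pixels whose values left the band
    for idx in sorted(ls.layers[0]):
        v = ls.layers[0][idx]
        if v < -0.5:
            set_layer(idx, -1, v)
        elif v >= 0.5:
            set_layer(idx, 1, v)

    # phase 4: extend the band where it now borders a sentinel
    for layer, sides in ((0, (-1, 1)), (1, (1,)), (-1, (-1,))):
        for idx in sorted(ls.layers[layer]):
            base = ls.values[ls.region.to_local(idx)]
            for n in _neighbors(idx):
                if not ls.region.contains(n):
                    continue
                lab = ls.layer_of(n)
                for side in sides:
                    sentinel = ls.interior_sentinel if side < 0 else ls.exterior_sentinel
                    if lab == sentinel:
                        v = base + side * 1.0
                        new_k = _bin_whitaker(v)
                        if abs(new_k) != 3:
                            set_layer(n, new_k, v)
    return rms


def update_shi(ls: SparseLevelSet, buffer: dict, notify=None):
    """Two-list interface update: boundary pixels switch sides when the
    PDE update favors it; lists are rebalanced so each stays one pixel
    thick.  Returns (switch count, rms change over interface pixels)."""

    def move(idx, layer, value):
        old = ls.values[ls.region.to_local(idx)]
        ls.set_layer(idx, layer, value)
        if notify is not None and old != value:
            notify(idx, float(old), float(value))

    interface = ls.interface_indices()
    switches = 0
    sq = 0.0
    # capture: outside boundary pixels whose update drives phi negative
    for idx in sorted(ls.layers[1]):
        if buffer.get(idx, 0.0) < 0.0:
            move(idx, -1, -1.0)
            sq += 4.0
            switches += 1
            for n in _neighbors(idx):
                if ls.region.contains(n) and ls.layer_of(n) == ls.exterior_sentinel:
                    move(n, 1, 1.0)
    # release: inside boundary pixels whose update drives phi positive
    for idx in sorted(ls.layers[-1]):
        if buffer.get(idx, 0.0) > 0.0:
            move(idx, 1, 1.0)
            sq += 4.0
            switches += 1
            for n in _neighbors(idx):
                if ls.region.contains(n) and ls.layer_of(n) == ls.interior_sentinel:
                    move(n, -1, -1.0)
    # integrity: each list stays exactly one pixel thick
    for idx in sorted(ls.layers[-1]):
        if not any(
            ls.region.contains(n) and ls.values[ls.region.to_local(n)] > 0
            for n in _neighbors(idx)
        ):
            old = ls.values[ls.region.to_local(idx)]
            ls.to_sentinel(idx, -1)
            if notify is not None:
                notify(idx, float(old), float(ls.interior_sentinel))
    for idx in sorted(ls.layers[1]):
        if not any(
            ls.region.contains(n) and ls.values[ls.region.to_local(n)] < 0
            for n in _neighbors(idx)
        ):
            old = ls.values[ls.region.to_local(idx)]
            ls.to_sentinel(idx, 1)
            if notify is not None:
                notify(idx, float(old), float(ls.exterior_sentinel))
    rms = math.sqrt(sq / len(interface)) if interface else 0.0
    return switches, rms


def update_malcolm(ls: SparseLevelSet, buffer: dict, notify=None):
    """Single-layer update: the boundary layer moves one pixel along the
    update's direction while staying a 1-px-thick inside boundary.
    Returns (switch count, rms change over layer pixels)."""

    def move(idx, layer, value):
        old = ls.values[ls.region.to_local(idx)]
        ls.set_layer(idx, layer, value)
        if notify is not None and old != value:
            notify(idx, float(old), float(value))

    def retire(idx, side):
        old = ls.values[ls.region.to_local(idx)]
        ls.to_sentinel(idx, side)
        new = ls.values[ls.region.to_local(idx)]
        if notify is not None and old != new:
            notify(idx, float(old), float(new))

    layer0 = sorted(ls.layers[0])
    switches = 0
    sq = 0.0
    for idx in layer0:
        u = buffer.get(idx, 0.0)
        if u < 0.0:  # grow: exterior neighbors join the boundary
            for n in _neighbors(idx):
                if ls.region.contains(n) and ls.layer_of(n) == ls.exterior_sentinel:
                    move(n, 0, 0.0)
                    sq += 1.0
                    switches += 1
        elif u > 0.0:  # shrink: pixel leaves, interior neighbors surface
            retire(idx, +1)
            sq += 1.0
            switches += 1
            for n in _neighbors(idx):
                if ls.region.contains(n) and ls.layer_of(n) == ls.interior_sentinel:
                    move(n, 0, 0.0)
    # boundary integrity: layer pixels with no exterior neighbor sink inside
    for idx in sorted(ls.layers[0]):
        if not any(
            ls.region.contains(n) and ls.values[ls.region.to_local(n)] > 0
            for n in _neighbors(idx)
        ):
            retire(idx, -1)
    rms = math.sqrt(sq / len(layer0)) if layer0 else 0.0
    return switches, rms


# ---------------------------------------------------------------------------
# energy (Chan-Vese systems)
# ---------------------------------------------------------------------------

def _chan_vese_energy(system: LevelSetSystem):
    """Variational energy, available only when every equation is built
    purely from Chan-Vese family terms; None otherwise."""
    total = 0.0
    for ls_id, eq in system.equations.items():
        terms = [t for _, t in eq.terms()]
        if not terms or not all(isinstance(t, _ChanVeseComponent) for t in terms):
            return None
        ls = system.level_sets.get_level_set(ls_id)
        img = system.image[ls.region.slices()]
        phi = ls.values
        shared = terms[0].shared
        eps = shared.epsilon
        h_in = np.asarray(heaviside_eps(-phi, eps))
        for _, t in eq.terms():
            from .terms import (ChanVeseAreaTerm, ChanVeseCurvatureTerm,
                                ChanVeseInsideFitTerm, ChanVeseOutsideFitTerm)
            if isinstance(t, ChanVeseInsideFitTerm):
                total += t.weight * float(((img - t.stats.c1) ** 2 * h_in).sum())
            elif isinstance(t, ChanVeseOutsideFitTerm):
                total += t.weight * float(((img - t.stats.c2) ** 2 * (1 - h_in)).sum())
            elif isinstance(t, ChanVeseAreaTerm):
                total += t.weight * float(h_in.sum())
            elif isinstance(t, ChanVeseCurvatureTerm):
                grads = np.gradient(phi) if phi.ndim > 1 else [np.gradient(phi)]
                gnorm = np.sqrt(sum(g**2 for g in grads))
                delta = np.asarray(dirac_eps(phi, eps))
                total += t.weight * float((delta * gnorm).sum())
    return total


# ---------------------------------------------------------------------------
# the engine
# ---------------------------------------------------------------------------

class LevelSetEvolution:
    """Runs the iteration loop over an assembled system.

    Loop order per iteration: allocate update buffers -> compute updates
    -> time step -> apply updates (firing per-pixel notifications in
    sparse mode) -> update term parameters -> accumulate RMS change ->
    reinitialization policy -> iteration event -> stopping check.
    """

    def __init__(self, system: LevelSetSystem, stopping, reinit: ReinitPolicy = None,
                 c_cfl: float = DEFAULT_C_CFL, dt_max: float = DEFAULT_DT_MAX,
                 hard_cap: int = DEFAULT_HARD_CAP, log_path=None):
        self.system = system
        self.stopping = stopping
        self.reinit = reinit if reinit is not None else ReinitPolicy()
        self.c_cfl = float(c_cfl)
        self.dt_max = float(dt_max)
        self.hard_cap = int(hard_cap)
        self.observers = ObserverRegistry()
        self.converged = None
        self.log_path = log_path

    def register_observer(self, callback) -> int:
        return self.observers.register(callback)

    def deregister_observer(self, handle: int):
        self.observers.deregister(handle)

    def _apply_updates(self, buffers, dt):
        per_ls = {}
        for ls_id, ls in self.system.level_sets.items():
            eq = self.system.equations.get_equation(ls_id)
            notify = (lambda idx, old, new, _eq=eq, _ls=ls:
                      _eq.update_pixel(_ls, idx, old, new))
            buf = buffers[ls_id]
            if isinstance(ls, DenseLevelSet):
                per_ls[ls_id] = update_dense(ls, buf, dt)
            elif ls.variant == "whitaker":
                per_ls[ls_id] = update_whitaker(ls, buf, dt, notify=notify)
            elif ls.variant == "shi":
                switches, rms = update_shi(ls, buf, notify=notify)
                per_ls[ls_id] = rms
            else:
                switches, rms = update_malcolm(ls, buf, notify=notify)
                per_ls[ls_id] = rms
        return per_ls

    def evolve(self) -> list:
        """Run to the stopping criterion (or the hard cap); returns the
        per-iteration state history."""
        system = self.system
        representation = system.level_sets.representation
        system.param_epoch += 1
        system.equations.initialize_parameters(system)
        history = []
        log_rows = []
        self.converged = False
        iteration = 0
        while iteration < self.hard_cap:
            iteration += 1
            buffers = compute_updates(system)
            _check_finite(buffers, iteration)
            dt = compute_time_step(buffers, representation, self.c_cfl, self.dt_max)
            per_ls = self._apply_updates(buffers, dt)
            system.param_epoch += 1
            system.equations.update_parameters(system)
            n = max(len(per_ls), 1)
            rms = math.sqrt(sum(v**2 for v in per_ls.values()) / n)
            state = EvolutionState(
                iteration=iteration,
                dt=dt,
                rms_change=rms,
                total_energy=_chan_vese_energy(system),
                per_level_set=MappingProxyType(dict(per_ls)),
            )
            apply_policy(system, state, self.reinit)
            history.append(state)
            log_rows.append(
                (iteration, dt, rms, "" if state.total_energy is None else state.total_energy)
            )
            self.observers.fire(
                IterationEvent(
                    iteration=iteration,
                    dt=dt,
                    rms_change=rms,
                    energy=state.total_energy,
                    per_level_set=state.per_level_set,
                )
            )
            if self.stopping.is_satisfied(state, system):
                self.converged = True
                break
        if self.log_path is not None:
            with open(self.log_path, "w", newline="") as fh:
                writer = csv.writer(fh)
                writer.writerow(["iteration", "dt", "rms_change", "energy"])
                writer.writerows(log_rows)
        return history
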