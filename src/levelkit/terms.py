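"""Pluggable per-pixel PDE terms.

Each level-set equation is a weighted sum of terms; a term evaluates the
*unweighted* contribution to ``d(phi)/dt`` at one grid point, reading
level-set quantities only through the shared :class:`QuantityCache` so the
same term runs unchanged on dense and sparse representations.

Sign conventions (inside-negative, ``phi < 0`` inside the object):

* ``propagation`` returns ``P * |grad phi|_upwind`` — a *positive* weight
  shrinks the interior, a negative weight grows it.
* ``advection`` returns ``sum_i A_i D_i phi`` with per-component upwinding;
  with ``A = grad g`` of an edge function the contour is attracted to edges
  from either side.
* the Chan–Vese family and the overlap penalty are sign-resolved below so
  that a pixel whose intensity is closer to the foreground mean is captured
  (phi pushed negative) and overlap pushes interiors apart.

The evolution engine only sums ``weight * term`` and scales by the time
step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import ConfigurationError, DegenerateInputError
from .grids import QuantityCache

__all__ = [
    "heaviside_eps",
    "dirac_eps",
    "EdgeFunctionParams",
    "edge_function",
    "RegionStats",
    "compute_region_means",
    "propagation_term",
    "advection_term",
    "curvature_term",
    "laplacian_term",
    "chan_vese_terms",
    "overlap_penalty_term",
    "li_regularization_term",
    "Term",
    "PropagationTerm",
    "AdvectionTerm",
    "CurvatureTerm",
    "LaplacianTerm",
    "ChanVeseStats",
    "ChanVeseCurvatureTerm",
    "ChanVeseAreaTerm",
    "ChanVeseInsideFitTerm",
    "ChanVeseOutsideFitTerm",
    "chan_vese_term_set",
    "OverlapPenaltyTerm",
    "LiRegularizationTerm",
    "geodesic_active_contour_terms",
]

DEFAULT_EPSILON = 1.5  # Heaviside/Dirac regularization width (px)
_LI_GRADIENT_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# regularized step / impulse functions
# ---------------------------------------------------------------------------

def heaviside_eps(z, epsilon: float = DEFAULT_EPSILON):
    """Smooth arctan Heaviside ``H_eps(z) = 1/2 (1 + 2/pi atan(z/eps))``."""
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    return 0.5 * (1.0 + (2.0 / math.pi) * np.arctan(np.asarray(z) / epsilon))


def dirac_eps(z, epsilon: float = DEFAULT_EPSILON):
    """``d H_eps / dz = eps / (pi (eps^2 + z^2))``."""
    if epsilon <= 0:
        raise ConfigurationError("epsilon must be positive")
    z = np.asarray(z)
    return (epsilon / math.pi) / (epsilon**2 + z**2)


# ---------------------------------------------------------------------------
# edge function
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EdgeFunctionParams:
    """Gaussian scale and exponent of the inverse-power edge indicator."""

    sigma: float = 1.0
    p: int = 2

    def __post_init__(self):
        if self.sigma < 0:
            raise ConfigurationError("sigma must be >= 0")
        if self.p < 1:
            raise ConfigurationError("exponent p must be >= 1")


def _smoothed_gradient_magnitude(image, sigma):
    image = np.asarray(image, dtype=float)
    smoothed = ndimage.gaussian_filter(image, sigma) if sigma > 0 else image
    grads = np.gradient(smoothed)
    if image.ndim == 1:
        grads = [grads]
    return np.sqrt(sum(g**2 for g in grads))


def edge_function(image, params: EdgeFunctionParams = EdgeFunctionParams()):
    """Edge indicator ``g = 1 / (1 + |grad(G_sigma * I)|^p)`` in (0, 1]."""
    mag = _smoothed_gradient_magnitude(image, params.sigma)
    return 1.0 / (1.0 + mag**params.p)


# ---------------------------------------------------------------------------
# region statistics (Chan–Vese)
# ---------------------------------------------------------------------------

@dataclass
class RegionStats:
    """Foreground/background mean intensities with the Heaviside width used."""

    c1: float
    c2: float
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be positive")
        if not (np.isfinite(self.c1) and np.isfinite(self.c2)):
            raise ConfigurationError("region means must be finite")


def compute_region_means(image, ls, epsilon: float = DEFAULT_EPSILON) -> RegionStats:
    """Heaviside-weighted foreground/background means over the level set's
    region.

    Under the inside-negative convention the interior indicator is
    ``H_eps(-phi)``:  ``c1 = sum(I H) / sum(H)``, ``c2`` with ``1 - H``.
    """
    img = np.asarray(image, dtype=float)[ls.region.slices()]
    w = np.asarray(heaviside_eps(-ls.values, epsilon))
    w1 = float(w.sum())
    w2 = float((1.0 - w).sum())
    if w1 < 1e-12 or w2 < 1e-12:
        raise DegenerateInputError("empty interior or exterior region")
    c1 = float((img * w).sum()) / w1
    c2 = float((img * (1.0 - w)).sum()) / w2
    return RegionStats(c1, c2, epsilon)


# ---------------------------------------------------------------------------
# functional term evaluations
# ---------------------------------------------------------------------------

def _sample(field, idx):
    """Scalar parameter fields may be constants or arrays over the image."""
    if np.isscalar(field) or isinstance(field, (int, float)):
        return float(field)
    return float(np.asarray(field)[tuple(idx)])


def propagation_term(idx, cache: QuantityCache, speed) -> float:
    """``P |grad phi|`` with the one-sided gradient selected by sign(P).

    Backward differences are used where ``P > 0`` and forward differences
    where ``P < 0`` so information flows from the front.
    """
    p = _sample(speed, idx)
    if p == 0.0:
        return 0.0
    g = cache.get("backward_gradient") if p > 0 else cache.get("forward_gradient")
    return p * float(np.sqrt(np.sum(g * g)))


def advection_term(idx, cache: QuantityCache, velocity) -> float:
    """``sum_i A_i D_i phi`` with per-component sign-based upwinding."""
    ndim = cache.ls.region.ndim
    if np.isscalar(velocity):
        a = np.full(ndim, float(velocity))
    else:
        velocity = np.asarray(velocity)
        if velocity.shape == (ndim,):
            a = velocity.astype(float)
        else:  # (ndim, *image_shape) component fields
            a = np.array([float(velocity[c][tuple(idx)]) for c in range(ndim)])
    total = 0.0
    bwd = fwd = None
    for c in range(ndim):
        if a[c] == 0.0:
            continue
        if a[c] > 0:
            if bwd is None:
                bwd = cache.get("backward_gradient")
            total += a[c] * float(bwd[c])
        else:
            if fwd is None:
                fwd = cache.get("forward_gradient")
            total += a[c] * float(fwd[c])
    return total


def curvature_term(idx, cache: QuantityCache, modifier=1.0) -> float:
    """``Z kappa |grad phi|`` with central-difference curvature and norm."""
    z = _sample(modifier, idx)
    if z == 0.0:
        return 0.0
    return z * cache.get("mean_curvature") * cache.get("gradient_norm")


def laplacian_term(idx, cache: QuantityCache) -> float:
    """Central-difference Laplacian of phi."""
    return float(cache.get("laplacian"))


def chan_vese_terms(idx, cache: QuantityCache, image, stats: RegionStats,
                    lambda1: float = 1.0, lambda2: float = 1.0,
                    nu: float = 0.0, mu: float = 0.0) -> float:
    """Full Chan–Vese gradient-flow update at one pixel (inside-negative).

    ``delta_eps(phi) [ mu kappa + nu + lambda1 (I - c1)^2
    - lambda2 (I - c2)^2 ]`` — a pixel whose intensity is closer to the
    foreground mean c1 receives a negative update (is captured).
    """
    phi = cache.get("value")
    delta = float(dirac_eps(phi, stats.epsilon))
    i = float(np.asarray(image)[tuple(idx)])
    total = nu + lambda1 * (i - stats.c1) ** 2 - lambda2 * (i - stats.c2) ** 2
    if mu != 0.0:
        total += mu * cache.get("mean_curvature")
    return delta * total


def overlap_penalty_term(idx, cache: QuantityCache, others, gamma: float = 1.0,
                         epsilon: float = DEFAULT_EPSILON) -> float:
    """Pairwise area-overlap penalty for concurrently evolving level sets.

    ``+gamma delta_eps(phi_i) sum_j H_eps(-phi_j)`` over the other level
    sets whose regions contain ``idx`` — positive (interior-shrinking)
    wherever another level set claims the pixel.
    """
    phi = cache.get("value")
    delta = float(dirac_eps(phi, epsilon))
    if delta == 0.0:
        return 0.0
    claimed = 0.0
    for other in others:
        if other is cache.ls or not other.region.contains(idx):
            continue
        claimed += float(heaviside_eps(-other.value(idx), epsilon))
    return gamma * delta * claimed


def li_regularization_term(idx, cache: QuantityCache) -> float:
    """Distance-keeping diffusion ``div[(1 - 1/|grad phi|) grad phi]``.

    Evaluated by central differences of the flux at the axis neighbors,
    with ``|grad phi|`` floored at 1e-3.  Zero for an exact signed-distance
    function; outward diffusion where ``|grad phi| > 1``, inward where
    ``< 1``.
    """
    ls = cache.ls
    ndim = ls.region.ndim
    idx = tuple(idx)

    def flux_component(point, comp):
        g = ls.gradient(point)
        norm = max(float(np.sqrt(np.sum(g * g))), _LI_GRADIENT_FLOOR)
        return (1.0 - 1.0 / norm) * float(g[comp])

    div = 0.0
    for ax in range(ndim):
        hi = list(idx)
        lo = list(idx)
        hi[ax] += 1
        lo[ax] -= 1
        div += (flux_component(tuple(hi), ax) - flux_component(tuple(lo), ax)) / (
            2.0 * ls.spacing[ax]
        )
    return div


# ---------------------------------------------------------------------------
# term objects
# ---------------------------------------------------------------------------

class Term:
    """One additive component of a level-set equation.

    ``evaluate`` returns the unweighted contribution; the stored ``weight``
    (the equation coefficient) is applied by the term container.
    ``requires`` names the cache quantities the term reads.
    """

    requires: frozenset = frozenset()

    def __init__(self, weight: float = 1.0, level_set_id=None):
        if not np.isfinite(weight):
            raise ConfigurationError("term weight must be finite")
        self.weight = float(weight)
        self.level_set_id = level_set_id
        self.system = None

    def bind(self, system):
        """Attach the assembled system (image, containers) to the term."""
        self.system = system

    def evaluate(self, idx, cache: QuantityCache) -> float:
        raise NotImplementedError

    def initialize_parameters(self, system):
        """Hook run once before iteration 0."""

    def update_parameters(self, system):
        """Hook run after each level-set update."""

    def update_pixel(self, ls, idx, old: float, new: float):
        """Per-pixel notification during sparse layer updates."""


class PropagationTerm(Term):
    requires = frozenset({"backward_gradient", "forward_gradient"})

    def __init__(self, speed=1.0, weight=1.0, level_set_id=None):
        super().__init__(weight, level_set_id)
        self.speed = speed

    def evaluate(self, idx, cache):
        return propagation_term(idx, cache, self.speed)


class AdvectionTerm(Term):
    requires = frozenset({"backward_gradient", "forward_gradient"})

    def __init__(self, velocity, weight=1.0, level_set_id=None):
        super().__init__(weight, level_set_id)
        self.velocity = velocity

    def evaluate(self, idx, cache):
        return advection_term(idx, cache, self.velocity)


class CurvatureTerm(Term):
    requires = frozenset({"mean_curvature", "gradient_norm"})

    def __init__(self, modifier=1.0, weight=1.0, level_set_id=None):
        super().__init__(weight, level_set_id)
        self.modifier = modifier

    def evaluate(self, idx, cache):
        return curvature_term(idx, cache, self.modifier)


class LaplacianTerm(Term):
    requires = frozenset({"laplacian"})

    def evaluate(self, idx, cache):
        return laplacian_term(idx, cache)


class ChanVeseStats:
    """Region means shared by the four Chan–Vese component terms.

    A full Heaviside-weighted recomputation runs at initialization and
    after every iteration; sparse layer updates patch the running sums
    incrementally per pixel so the statistics stay current mid-iteration.
    """

    def __init__(self, epsilon: float = DEFAULT_EPSILON):
        self.epsilon = float(epsilon)
        self.stats: RegionStats = None
        self._s1 = self._w1 = self._s2 = self._w2 = 0.0
        self._epoch = None

    def refresh(self, image, ls, epoch=None):
        if epoch is not None and epoch == self._epoch:
            return
        img = np.asarray(image, dtype=float)[ls.region.slices()]
        w = np.asarray(heaviside_eps(-ls.values, self.epsilon))
        self._w1 = float(w.sum())
        self._s1 = float((img * w).sum())
        self._w2 = float((1.0 - w).sum())
        self._s2 = float((img * (1.0 - w)).sum())
        self._epoch = epoch
        self._derive()

    def _derive(self):
        if self._w1 < 1e-12 or self._w2 < 1e-12:
            raise DegenerateInputError("empty interior or exterior region")
        self.stats = RegionStats(self._s1 / self._w1, self._s2 / self._w2, self.epsilon)

    def update_pixel(self, image, idx, old: float, new: float):
        i = float(np.asarray(image)[tuple(idx)])
        dw = float(heaviside_eps(-new, self.epsilon)) - float(
            heaviside_eps(-old, self.epsilon)
        )
        if dw == 0.0:
            return
        self._w1 += dw
        self._s1 += i * dw
        self._w2 -= dw
        self._s2 -= i * dw
        self._derive()


class _ChanVeseComponent(Term):
    """Shared machinery: keep the common statistics current."""

    def __init__(self, stats: ChanVeseStats = None, weight=1.0, level_set_id=None):
        super().__init__(weight, level_set_id)
        self.shared = stats if stats is not None else ChanVeseStats()

    def _ls(self, system):
        return system.level_sets.get_level_set(self.level_set_id)

    def initialize_parameters(self, system):
        self.shared.refresh(system.image, self._ls(system), epoch=("init", system.param_epoch))

    def update_parameters(self, system):
        self.shared.refresh(system.image, self._ls(system), epoch=("update", system.param_epoch))

    def update_pixel(self, ls, idx, old, new):
        self.shared.update_pixel(self.system.image, idx, old, new)

    @property
    def stats(self) -> RegionStats:
        return self.shared.stats


class ChanVeseCurvatureTerm(_ChanVeseComponent):
    """``delta_eps(phi) kappa`` — curve-length regularization (weight mu)."""

    requires = frozenset({"value", "mean_curvature"})

    def evaluate(self, idx, cache):
        phi = cache.get("value")
        return float(dirac_eps(phi, self.shared.epsilon)) * cache.get("mean_curvature")


class ChanVeseAreaTerm(_ChanVeseComponent):
    """``+delta_eps(phi)`` — interior-area penalty (weight nu shrinks)."""

    requires = frozenset({"value"})

    def evaluate(self, idx, cache):
        return float(dirac_eps(cache.get("value"), self.shared.epsilon))


class ChanVeseInsideFitTerm(_ChanVeseComponent):
    """``+delta_eps(phi) (I - c1)^2`` — expels pixels unlike the interior."""

    requires = frozenset({"value"})

    def evaluate(self, idx, cache):
        i = float(np.asarray(self.system.image)[tuple(idx)])
        delta = float(dirac_eps(cache.get("value"), self.shared.epsilon))
        return delta * (i - self.stats.c1) ** 2


class ChanVeseOutsideFitTerm(_ChanVeseComponent):
    """``-delta_eps(phi) (I - c2)^2`` — captures pixels unlike the exterior."""

    requires = frozenset({"value"})

    def evaluate(self, idx, cache):
        i = float(np.asarray(self.system.image)[tuple(idx)])
        delta = float(dirac_eps(cache.get("value"), self.shared.epsilon))
        return -delta * (i - self.stats.c2) ** 2


def chan_vese_term_set(lambda1=1.0, lambda2=1.0, nu=0.0, mu=1.0,
                       epsilon=DEFAULT_EPSILON, level_set_id=None):
    """The four separately-registerable Chan–Vese terms sharing one
    statistics object, weighted (mu, nu, lambda1, lambda2)."""
    shared = ChanVeseStats(epsilon)
    terms = []
    if mu != 0.0:
        terms.append(ChanVeseCurvatureTerm(shared, weight=mu, level_set_id=level_set_id))
    if nu != 0.0:
        terms.append(ChanVeseAreaTerm(shared, weight=nu, level_set_id=level_set_id))
    terms.append(ChanVeseInsideFitTerm(shared, weight=lambda1, level_set_id=level_set_id))
    terms.append(ChanVeseOutsideFitTerm(shared, weight=lambda2, level_set_id=level_set_id))
    return terms


class OverlapPenaltyTerm(Term):
    """``delta_eps(phi_i) sum_{j != i} H_eps(-phi_j)`` — the weight is the
    penalty strength gamma."""

    requires = frozenset({"value"})

    def __init__(self, weight=1.0, level_set_id=None, epsilon=DEFAULT_EPSILON):
        super().__init__(weight, level_set_id)
        self.epsilon = float(epsilon)

    def evaluate(self, idx, cache):
        others = (
            ls
            for i, ls in self.system.level_sets.items()
            if i != self.level_set_id
        )
        return overlap_penalty_term(idx, cache, others, gamma=1.0, epsilon=self.epsilon)


class LiRegularizationTerm(Term):
    requires = frozenset()

    def evaluate(self, idx, cache):
        return li_regularization_term(idx, cache)


def geodesic_active_contour_terms(image, params: EdgeFunctionParams = EdgeFunctionParams(),
                                  alpha=1.0, beta=1.0, gamma=1.0, level_set_id=None):
    """Advection + propagation + curvature terms of the geodesic model.

    ``A = grad g``, ``P = g``, ``Z = g`` with the edge indicator ``g``
    precomputed once.  Positive ``beta`` shrinks the contour onto edges;
    negative grows it.
    """
    g = edge_function(image, params)
    grads = np.gradient(g)
    if np.asarray(image).ndim == 1:
        grads = [grads]
    grad_g = np.stack(grads)
    return [
        AdvectionTerm(grad_g, weight=alpha, level_set_id=level_set_id),
        PropagationTerm(g, weight=beta, level_set_id=level_set_id),
        CurvatureTerm(g, weight=gamma, level_set_id=level_set_id),
    ]
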