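"""Pluggable stopping criteria.

A criterion inspects the per-iteration evolution state (and, for the
captured-points rule, the level sets themselves) and reports whether the
run should halt.  Criteria compose with short-circuit any/all semantics.
"""

from __future__ import annotations

from .errors import ConfigurationError

__all__ = [
    "StoppingCriterion",
    "MaxIterations",
    "RmsChangeBelow",
    "EnergyDeltaBelow",
    "PointsCaptured",
    "CombinedCriterion",
    "combine",
]


class StoppingCriterion:
    def is_satisfied(self, state, system) -> bool:
        raise NotImplementedError


class MaxIterations(StoppingCriterion):
    def __init__(self, n: int):
        if n < 1:
            raise ConfigurationError("iteration limit must be positive")
        self.n = int(n)

    def is_satisfied(self, state, system):
        return state.iteration >= self.n


class RmsChangeBelow(StoppingCriterion):
    def __init__(self, threshold: float):
        if threshold <= 0:
            raise ConfigurationError("rms threshold must be positive")
        self.threshold = float(threshold)

    def is_satisfied(self, state, system):
        return state.rms_change < self.threshold


class EnergyDeltaBelow(StoppingCriterion):
    """|E_t - E_{t-1}| < threshold; requires an energy-tracking equation."""

    def __init__(self, threshold: float):
        if threshold <= 0:
            raise ConfigurationError("energy threshold must be positive")
        self.threshold = float(threshold)
        self._previous = None

    def is_satisfied(self, state, system):
        if state.total_energy is None:
            raise ConfigurationError(
                "energy stopping criterion requires Chan-Vese energy tracking"
            )
        previous, self._previous = self._previous, state.total_energy
        if previous is None:
            return False
        return abs(state.total_energy - previous) < self.threshold


class PointsCaptured(StoppingCriterion):
    """Stop when a fraction of target points lie inside some level set.

    Containment means ``phi < tolerance`` (default strict interior,
    tolerance 0); a positive tolerance accepts proximity to the zero
    level.
    """

    def __init__(self, points, fraction: float, tolerance: float = 0.0):
        if not points:
            raise ConfigurationError("points_captured needs at least one point")
        if not 0 < fraction <= 1:
            raise ConfigurationError("fraction must be in (0, 1]")
        self.points = [tuple(p) for p in points]
        self.fraction = float(fraction)
        self.tolerance = float(tolerance)

    def is_satisfied(self, state, system):
        captured = 0
        for point in self.points:
            for _, ls in system.level_sets.items():
                if ls.region.contains(point) and ls.value(point) < self.tolerance:
                    captured += 1
                    break
        return captured / len(self.points) >= self.fraction


class CombinedCriterion(StoppingCriterion):
    def __init__(self, criteria, mode: str = "any"):
        if not criteria:
            raise ConfigurationError("combine needs at least one criterion")
        if mode not in ("any", "all"):
            raise ConfigurationError("mode must be 'any' or 'all'")
        self.criteria = list(criteria)
        self.mode = mode

    def is_satisfied(self, state, system):
        op = any if self.mode == "any" else all
        return op(c.is_satisfied(state, system) for c in self.criteria)


def combine(criteria, mode: str = "any") -> StoppingCriterion:
    """Short-circuit disjunction/conjunction of criteria."""
    return CombinedCriterion(criteria, mode)
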