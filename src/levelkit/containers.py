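"""Identifier-keyed containers linking level sets, terms, and equations.

A system of M concurrently evolving level sets is described by one
:class:`LevelSetContainer` (id -> level-set function), one
:class:`EquationContainer` (id -> :class:`TermContainer`) and a shared
domain map.  The same id keys all three, and ids may appear or disappear
between iterations (dynamic seeding/termination).
"""

from __future__ import annotations

from .errors import ConfigurationError, IdError
from .grids import QuantityCache

__all__ = ["LevelSetContainer", "TermContainer", "EquationContainer"]


class LevelSetContainer:
    """Associative store of level-set functions keyed by identifier.

    All members must share one representation family (dense, or one sparse
    variant); mixed systems are rejected at insertion.
    """

    def __init__(self):
        self._entries = {}
        self.domain_map = None

    def add_level_set(self, ls_id, ls):
        if ls_id in self._entries:
            raise IdError(f"level-set id {ls_id!r} already present")
        if self._entries:
            family = next(iter(self._entries.values())).representation
            if ls.representation != family:
                raise ConfigurationError(
                    f"mixed representation families: {family} vs {ls.representation}"
                )
        self._entries[ls_id] = ls

    def get_level_set(self, ls_id):
        try:
            return self._entries[ls_id]
        except KeyError:
            raise IdError(f"no level set with id {ls_id!r}") from None

    def remove_level_set(self, ls_id):
        if ls_id not in self._entries:
            raise IdError(f"no level set with id {ls_id!r}")
        del self._entries[ls_id]

    def ids(self):
        return sorted(self._entries)

    def items(self):
        for ls_id in self.ids():
            yield ls_id, self._entries[ls_id]

    def __iter__(self):
        return iter(self.ids())

    def __len__(self):
        return len(self._entries)

    def __contains__(self, ls_id):
        return ls_id in self._entries

    @property
    def representation(self):
        if not self._entries:
            return None
        return next(iter(self._entries.values())).representation


class TermContainer:
    """Ordered (dense integer index -> term) collection driving one level set."""

    def __init__(self, level_set_id=None):
        self.level_set_id = level_set_id
        self._terms = {}

    def add_term(self, term):
        """Append at the next free index after the current maximum."""
        index = max(self._terms, default=-1) + 1
        term.level_set_id = self.level_set_id
        self._terms[index] = term
        return index

    def push_term(self, index, term):
        """Insert at an explicit index; occupied indices are an error."""
        if index in self._terms:
            raise IdError(f"term index {index} already occupied")
        term.level_set_id = self.level_set_id
        self._terms[index] = term

    def remove_term(self, index):
        if index not in self._terms:
            raise IdError(f"no term at index {index}")
        del self._terms[index]

    def terms(self):
        for index in sorted(self._terms):
            yield index, self._terms[index]

    def __len__(self):
        return len(self._terms)

    def evaluate(self, idx, cache: QuantityCache) -> float:
        """Weighted sum of all terms at ``idx`` with one shared cache."""
        if not self._terms:
            raise ConfigurationError(
                f"equation for level set {self.level_set_id!r} has no terms"
            )
        total = 0.0
        for _, term in self.terms():
            if term.weight == 0.0:
                continue
            total += term.weight * term.evaluate(idx, cache)
        return total

    def bind(self, system):
        for _, term in self.terms():
            term.bind(system)

    def initialize_parameters(self, system):
        for _, term in self.terms():
            term.initialize_parameters(system)

    def update_parameters(self, system):
        for _, term in self.terms():
            term.update_parameters(system)

    def update_pixel(self, ls, idx, old, new):
        for _, term in self.terms():
            term.update_pixel(ls, idx, old, new)


class EquationContainer:
    """id -> term container; one equation per level set in the system."""

    def __init__(self):
        self._equations = {}

    def add_equation(self, ls_id, term_container: TermContainer):
        if ls_id in self._equations:
            raise IdError(f"equation for id {ls_id!r} already present")
        term_container.level_set_id = ls_id
        for _, term in term_container.terms():
            term.level_set_id = ls_id
        self._equations[ls_id] = term_container

    def get_equation(self, ls_id) -> TermContainer:
        try:
            return self._equations[ls_id]
        except KeyError:
            raise IdError(f"no equation for id {ls_id!r}") from None

    def remove_equation(self, ls_id):
        if ls_id not in self._equations:
            raise IdError(f"no equation for id {ls_id!r}")
        del self._equations[ls_id]

    def ids(self):
        return sorted(self._equations)

    def items(self):
        for ls_id in self.ids():
            yield ls_id, self._equations[ls_id]

    def __contains__(self, ls_id):
        return ls_id in self._equations

    def __len__(self):
        return len(self._equations)

    def bind(self, system):
        for _, eq in self.items():
            eq.bind(system)

    def initialize_parameters(self, system):
        for _, eq in self.items():
            eq.initialize_parameters(system)

    def update_parameters(self, system):
        for _, eq in self.items():
            eq.update_parameters(system)
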