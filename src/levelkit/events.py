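"""Per-iteration observer/event mechanism (subject/observer pattern).

The evolution engine fires one read-only :class:`IterationEvent` per
completed iteration to all registered observers in registration order.
Observers may log, snapshot, or drive interactive seeding between
iterations; they receive state, not the mutable level sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import MappingProxyType

from .errors import HandleError

__all__ = ["IterationEvent", "ObserverRegistry"]


@dataclass(frozen=True)
class IterationEvent:
    """Snapshot of one completed iteration."""

    iteration: int
    dt: float
    rms_change: float
    energy: float = None
    per_level_set: MappingProxyType = field(default_factory=lambda: MappingProxyType({}))


class ObserverRegistry:
    """Ordered callback registry with deregistration handles."""

    def __init__(self):
        self._observers = {}
        self._next_handle = 0

    def register(self, callback) -> int:
        handle = self._next_handle
        self._next_handle += 1
        self._observers[handle] = callback
        return handle

    def deregister(self, handle: int):
        if handle not in self._observers:
            raise HandleError(f"observer handle {handle} is not registered")
        del self._observers[handle]

    def fire(self, event: IterationEvent):
        """Invoke all observers in registration order.

        An exception in a callback aborts the run with iteration context.
        """
        for handle in sorted(self._observers):
            try:
                self._observers[handle](event)
            except Exception as exc:
                raise RuntimeError(
                    f"observer {handle} failed at iteration {event.iteration}"
                ) from exc

    def __len__(self):
        return len(self._observers)
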