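"""Typed gait events (initial contact / foot off) and ordered event series."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

__all__ = ["GaitEvent", "EventSeries", "IC", "FO"]

IC = "IC"
FO = "FO"
_KINDS = (IC, FO)


@dataclass(frozen=True)
class GaitEvent:
    """One gait event.

    ``kind`` is ``"IC"`` (initial contact, foot strikes the ground) or
    ``"FO"`` (foot off, foot leaves the ground). ``index`` is the 0-based
    sample index in the source signal, or ``None`` for events loaded from a
    file without signal context. ``time`` is in seconds.
    """

    kind: str
    index: Optional[int]
    time: float

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")


@dataclass
class EventSeries:
    """Ordered list of gait events with a provenance label.

    ``source`` is a free label, conventionally ``"detected"``,
    ``"reference"`` or ``"truth"``. Times must be strictly increasing;
    kinds normally alternate IC, FO, IC, ... but a detected or reference
    series may contain gaps (e.g. consecutive ICs after a missed FO).
    """

    events: list[GaitEvent] = field(default_factory=list)
    source: str = "detected"

    def __post_init__(self) -> None:
        times = [e.time for e in self.events]
        for i in range(1, len(times)):
            if times[i] <= times[i - 1]:
                raise ValueError(
                    f"event times must be strictly increasing; "
                    f"t[{i}]={times[i]} <= t[{i - 1}]={times[i - 1]}"
                )

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[GaitEvent]:
        return iter(self.events)

    def __getitem__(self, i):
        return self.events[i]

    def of_kind(self, kind: str) -> list[GaitEvent]:
        """Events of one kind, in temporal order."""
        return [e for e in self.events if e.kind == kind]

    @property
    def times(self) -> list[float]:
        return [e.time for e in self.events]

    @property
    def kinds(self) -> list[str]:
        return [e.kind for e in self.events]

    def is_alternating(self) -> bool:
        """True if kinds strictly alternate (IC, FO, IC, ...)."""
        kinds = self.kinds
        return all(kinds[i] != kinds[i - 1] for i in range(1, len(kinds)))
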