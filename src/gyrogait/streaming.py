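"""Online (sample-by-sample) version of the event detector.

The streaming detector emits exactly the events the batch detector finds on
the concatenated signal, but incrementally: each pushed sample may release
zero or more events. Because a foot-off candidate must be validated as the
unique minimum of a window extending ``fo_lookahead`` samples ahead, an FO
at index ``n`` is emitted once sample ``n + fo_lookahead`` has arrived —
15 samples, i.e. 120 ms at 125 Hz, in the default configuration. ``close()``
flushes decisions whose windows are clipped by the end of the signal.
"""

from __future__ import annotations

from typing import Iterable, Optional

from .config import DetectorConfig
from .detector import SwingTracker, fo_window_ok
from .events import FO, IC, EventSeries, GaitEvent

__all__ = ["StreamingDetector", "stream_detect"]

_SEARCH = "search_swing"
_SWING = "swing"
_SEEK_IC = "seek_ic"
_SEEK_FO = "seek_fo"


class StreamingDetector:
    """Incremental rule-based gait event detector.

    Parameters
    ----------
    cfg : DetectorConfig, optional
    fs : float
        Sampling rate of the incoming stream, Hz.
    t0 : float
        Time of the first sample, seconds.

    Attributes
    ----------
    events : list of GaitEvent
        All events emitted so far.
    latencies : list of int
        Emission latency of each event, in samples: the number of samples
        that had to arrive after the event's own sample before it could be
        emitted (0 means emitted the moment its sample arrived).
    """

    def __init__(
        self,
        cfg: DetectorConfig | None = None,
        fs: float = 125.0,
        t0: float = 0.0,
    ) -> None:
        self.cfg = cfg or DetectorConfig()
        self.fs = fs
        self.t0 = t0
        self.events: list[GaitEvent] = []
        self.latencies: list[int] = []
        self.missed_fo_count = 0
        self._buf: list[float] = []
        self._state = _SEARCH
        self._cursor = 0
        self._closed = False
        # per-state registers
        self._az: Optional[int] = None
        self._run = 0
        self._qualified = False
        self._dz: Optional[int] = None
        self._ic: Optional[int] = None
        self._fo_start = 0
        self._tracker: Optional[SwingTracker] = None

    def push(self, x: float) -> list[GaitEvent]:
        """Feed one sample; return events decided by its arrival."""
        if self._closed:
            raise RuntimeError("detector already closed")
        self._buf.append(float(x))
        return self._advance(closing=False)

    def extend(self, xs: Iterable[float]) -> list[GaitEvent]:
        """Feed several samples; return events decided while feeding."""
        out: list[GaitEvent] = []
        for x in xs:
            out.extend(self.push(x))
        return out

    def close(self) -> list[GaitEvent]:
        """Signal end of stream; flush end-clipped decisions."""
        if self._closed:
            return []
        self._closed = True
        return self._advance(closing=True)

    def event_series(self) -> EventSeries:
        return EventSeries(list(self.events), source="detected")

    # -- internals ---------------------------------------------------------

    def _emit(self, kind: str, index: int) -> GaitEvent:
        ev = GaitEvent(kind, index, self.t0 + index / self.fs)
        self.events.append(ev)
        self.latencies.append(len(self._buf) - 1 - index)
        return ev

    def _advance(self, closing: bool) -> list[GaitEvent]:
        g = self._buf
        cfg = self.cfg
        out: list[GaitEvent] = []
        while True:
            n = self._cursor
            n_buf = len(g)
            if n >= n_buf:
                break
            if self._state == _SEARCH:
                prev = g[n - 1] if n > 0 else 0.0
                if prev <= 0.0 < g[n]:
                    self._state = _SWING
                    self._az = n
                    self._run = 1 if g[n] >= cfg.swing_threshold else 0
                    self._qualified = self._run >= cfg.swing_min_samples
                self._cursor = n + 1
            elif self._state == _SWING:
                if g[n] <= 0.0:
                    if self._qualified:
                        self._dz = n
                        self._state = _SEEK_IC
                    else:
                        self._state = _SEARCH
                    self._cursor = n + 1
                else:
                    if g[n] >= cfg.swing_threshold:
                        self._run += 1
                        if self._run >= cfg.swing_min_samples:
                            self._qualified = True
                    else:
                        self._run = 0
                    self._cursor = n + 1
            elif self._state == _SEEK_IC:
                if n + 1 >= n_buf:
                    # need the next sample to confirm a local minimum; a
                    # signal ending mid-descent drops the partial cycle
                    break
                if g[n] < 0.0 and g[n] < g[n - 1] and g[n] <= g[n + 1]:
                    out.append(self._emit(IC, n))
                    self._begin_fo_search(n)
                else:
                    self._cursor = n + 1
            elif self._state == _SEEK_FO:
                # every decision at index n may need the full lookahead
                if n + cfg.fo_lookahead >= n_buf and not closing:
                    break
                if n > self._ic:
                    self._tracker.feed(g[n], n)
                if (
                    cfg.preempt_fo_on_new_swing
                    and n >= self._fo_start
                    and self._tracker.in_qualified_wave
                ):
                    self.missed_fo_count += 1
                    self._state = _SWING
                    self._az = self._tracker.az
                    self._run = self._tracker.run
                    self._qualified = True
                    self._cursor = n + 1
                elif n >= self._fo_start and fo_window_ok(g, n, cfg):
                    out.append(self._emit(FO, n))
                    self._state = _SEARCH
                    self._cursor = n + 1
                else:
                    self._cursor = n + 1
        return out

    def _begin_fo_search(self, ic: int) -> None:
        cfg = self.cfg
        self._ic = ic
        self._fo_start = ic + cfg.wait_samples(self.fs)
        self._tracker = SwingTracker(cfg, prev=self._buf[ic])
        self._state = _SEEK_FO
        # degenerate zero waiting time: the IC sample itself is a candidate
        self._cursor = ic if self._fo_start <= ic else ic + 1


def stream_detect(
    samples: Iterable[float],
    cfg: DetectorConfig | None = None,
    fs: float = 125.0,
    t0: float = 0.0,
) -> tuple[EventSeries, list[int]]:
    """Run the streaming detector over an iterable of samples.

    Returns the detected :class:`EventSeries` (identical to
    :func:`gyrogait.detector.detect_events` on the same samples) and the
    per-event emission latencies in samples.
    """
    det = StreamingDetector(cfg, fs=fs, t0=t0)
    det.extend(samples)
    det.close()
    return det.event_series(), det.latencies
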