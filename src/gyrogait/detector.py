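"""Rule-based detection of initial contact and foot off from shank angular velocity.

The algorithm evaluates the signal sample by sample and cycles through four
phases, mirroring the structure of a gait cycle:

1. **Swing search.** Find an ascending zero crossing (AZ) followed by a
   positive wave that stays at or above ``swing_threshold`` (+60 deg/s) for
   at least ``swing_min_samples`` consecutive samples before the next
   descending zero crossing (DZ). Waves that never sustain the threshold are
   discarded and the search resumes, which is what keeps the detector quiet
   during standing-still shuffling.
2. **Initial contact.** The first negative local minimum after the DZ is IC
   (the dip produced when the foot hits the ground).
3. **Waiting time.** A refractory interval after IC skips the
   loading-response oscillations that follow foot impact.
4. **Foot off.** The first sample at or below ``fo_threshold`` (−60 deg/s)
   that is the unique minimum of a 26-sample window (10 behind, 15 ahead)
   is FO. Optionally, a new qualifying swing wave occurring during this
   search preempts it: the FO is missed and the wave is processed as the
   next swing (with its following minimum emitted as an IC) — the behaviour
   observed on real stair-ascent signals whose stance phase can resemble a
   swing. After FO the algorithm starts again.

Zero crossings use half-open conventions so that each crossing is a unique
sample even on an exactly-zero baseline: AZ at the first ``n`` with
``g(n−1) ≤ 0 < g(n)`` (the sample before the signal start is taken as 0)
and DZ at the first ``n`` with ``g(n−1) > 0 ≥ g(n)``.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np

from .config import DetectorConfig
from .events import FO, IC, EventSeries, GaitEvent
from .signal import GyroSignal

__all__ = [
    "find_swing",
    "detect_ic",
    "detect_fo",
    "detect_events",
]

logger = logging.getLogger(__name__)


class SwingTracker:
    """Incremental swing-wave detector shared by the batch and streaming paths.

    Feed samples in order; the tracker reports when a qualified positive
    wave (ascending zero crossing + sustained threshold) is in progress and
    returns ``(az, dz)`` when such a wave ends with a descending zero
    crossing.
    """

    def __init__(self, cfg: DetectorConfig, prev: float) -> None:
        self._cfg = cfg
        self._prev = prev
        self.in_wave = False
        self.az: Optional[int] = None
        self.run = 0
        self.qualified = False

    @property
    def in_qualified_wave(self) -> bool:
        return self.in_wave and self.qualified

    def feed(self, x: float, index: int) -> Optional[tuple[int, int]]:
        """Process sample ``x`` at ``index``; return (az, dz) if a qualified
        wave just ended with its descending zero crossing at ``index``."""
        cfg = self._cfg
        result = None
        if self.in_wave:
            if x <= 0.0:
                if self.qualified:
                    result = (self.az, index)
                self.in_wave = False
                self.qualified = False
                self.run = 0
            else:
                self.run = self.run + 1 if x >= cfg.swing_threshold else 0
                if self.run >= cfg.swing_min_samples:
                    self.qualified = True
        elif self._prev <= 0.0 < x:
            self.in_wave = True
            self.az = index
            self.run = 1 if x >= cfg.swing_threshold else 0
            self.qualified = self.run >= cfg.swing_min_samples
        self._prev = x
        return result


def fo_window_ok(g, n: int, cfg: DetectorConfig) -> bool:
    """True if sample ``n`` satisfies both foot-off conditions.

    (a) ``g[n]`` at or below ``fo_threshold``; (b) ``g[n]`` is the strict
    (unique) minimum of the window ``[n − fo_behind, n + fo_lookahead]``,
    clipped at the signal ends. An equal value anywhere else in the window
    disqualifies the candidate — a broad trough of equal-depth local minima
    therefore yields no foot off at all.

    ``g`` may be any float sequence (array or growing buffer).
    """
    if g[n] > cfg.fo_threshold:
        return False
    lo = max(0, n - cfg.fo_behind)
    hi = min(len(g) - 1, n + cfg.fo_lookahead)
    window = np.asarray(g[lo : hi + 1])
    below = window <= g[n]
    # exactly one sample (n itself) may be <= g[n]
    return int(np.count_nonzero(below)) == 1


def find_swing(
    signal: GyroSignal, start: int, cfg: DetectorConfig | None = None
) -> Optional[tuple[int, int]]:
    """Find the first qualifying swing wave at or after ``start``.

    Returns ``(az, dz)`` — the ascending zero crossing opening the wave and
    the descending zero crossing closing it — or ``None`` if no wave before
    the end of the signal sustains ``swing_threshold`` for
    ``swing_min_samples`` consecutive samples. Waves that end (cross back
    to ≤ 0) without qualifying are discarded and the search resumes.
    """
    cfg = cfg or DetectorConfig()
    g = signal.samples
    n_samples = len(g)
    if not (0 <= start <= n_samples):
        raise ValueError(f"start index {start} outside signal of length {n_samples}")
    prev = g[start - 1] if start > 0 else 0.0
    tracker = SwingTracker(cfg, prev)
    for n in range(start, n_samples):
        ended = tracker.feed(g[n], n)
        if ended is not None:
            return ended
    return None


def detect_ic(signal: GyroSignal, dz_index: int) -> Optional[int]:
    """First negative local minimum after the descending zero crossing.

    Returns the smallest ``n > dz_index`` with ``g(n) < 0``,
    ``g(n) < g(n−1)`` and ``g(n) ≤ g(n+1)`` — on a flat plateau the first
    sample wins — or ``None`` if the signal ends first (a partial cycle is
    dropped).
    """
    g = signal.samples
    for n in range(dz_index + 1, len(g) - 1):
        if g[n] < 0.0 and g[n] < g[n - 1] and g[n] <= g[n + 1]:
            return n
    return None


def _detect_fo(
    signal: GyroSignal, ic_index: int, cfg: DetectorConfig
) -> tuple[Optional[int], bool, Optional[int]]:
    """Foot-off search with preemption bookkeeping.

    Returns ``(fo_index, preempted, preempt_az)``. ``fo_index`` is None when
    no foot off was found; ``preempted`` is True when a new qualifying swing
    aborted the search, in which case ``preempt_az`` is that wave's
    ascending zero crossing (where detection resumes).
    """
    g = signal.samples
    n_samples = len(g)
    search_start = ic_index + cfg.wait_samples(signal.fs)
    # degenerate zero waiting time: the IC sample itself is a candidate
    if search_start <= ic_index and fo_window_ok(g, ic_index, cfg):
        return ic_index, False, None
    tracker = SwingTracker(cfg, prev=g[ic_index])
    for n in range(ic_index + 1, n_samples):
        tracker.feed(g[n], n)
        if (
            cfg.preempt_fo_on_new_swing
            and n >= search_start
            and tracker.in_qualified_wave
        ):
            return None, True, tracker.az
        if n >= search_start and fo_window_ok(g, n, cfg):
            return n, False, None
    return None, False, None


def detect_fo(
    signal: GyroSignal, ic_index: int, cfg: DetectorConfig | None = None
) -> tuple[Optional[int], bool]:
    """Find the foot off following the initial contact at ``ic_index``.

    The search starts ``round(wait_time_ms · fs / 1000)`` samples after IC.
    Returns ``(fo_index or None, preempted)``; ``preempted`` is True when
    ``preempt_fo_on_new_swing`` is enabled and a qualifying swing wave began
    before a foot off was found.
    """
    cfg = cfg or DetectorConfig()
    if not (0 <= ic_index < len(signal)):
        raise ValueError(f"ic_index {ic_index} outside signal")
    fo, preempted, _ = _detect_fo(signal, ic_index, cfg)
    return fo, preempted


def detect_events(
    signal: GyroSignal, cfg: DetectorConfig | None = None
) -> EventSeries:
    """Run the full detection cycle over a signal and return all events.

    The state machine (swing search → IC → wait → FO → swing search) starts
    at sample 0 and runs to the end of the signal. On FO preemption the miss
    is logged and detection continues from the new swing wave, so the output
    may contain consecutive ICs. Sub-threshold movement (standing-still
    wiggle) produces no events; an empty signal produces an empty series.
    """
    cfg = cfg or DetectorConfig()
    events: list[GaitEvent] = []
    pos = 0
    while True:
        swing = find_swing(signal, pos, cfg)
        if swing is None:
            break
        az, dz = swing
        logger.debug("swing wave: az=%d dz=%d", az, dz)
        ic = detect_ic(signal, dz)
        if ic is None:
            logger.debug("signal ended before IC after dz=%d", dz)
            break
        events.append(GaitEvent(IC, ic, signal.time_of(ic)))
        logger.debug("IC at %d", ic)
        fo, preempted, preempt_az = _detect_fo(signal, ic, cfg)
        if fo is not None:
            events.append(GaitEvent(FO, fo, signal.time_of(fo)))
            logger.debug("FO at %d", fo)
            pos = fo + 1
        elif preempted:
            logger.debug(
                "FO after IC=%d missed: preempted by new swing at az=%d",
                ic,
                preempt_az,
            )
            pos = preempt_az
        else:
            logger.debug("FO search after IC=%d reached end of signal", ic)
            break
    return EventSeries(events, source="detected")
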