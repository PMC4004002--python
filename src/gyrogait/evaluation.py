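"""Timing and reliability evaluation of detected events against a reference.

Detected events are paired with reference events of the same kind; the
signed timing difference of a pair is ``t_reference − t_detected`` in ms,
so a positive difference means the detector fired earlier than the
reference. Per subject, the mean difference (MD) and absolute mean
difference (AMD) summarise bias and magnitude of the disagreement; across
subjects, the unweighted means of the per-subject values are reported with
a Student-t 95% confidence interval (appropriate for the small cohorts,
n = 6–7, this protocol targets). Reliability is quantified as success in
detection: the percentage of reference events that were correctly detected
(neither missed nor duplicated). Difference distributions are binned from
−400 to +400 ms in 10 ms intervals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .events import FO, IC, EventSeries, GaitEvent

__all__ = [
    "MatchedPair",
    "MatchResult",
    "TimingSummary",
    "DifferenceHistogram",
    "match_events",
    "timing_differences",
    "summarize_subject",
    "summarize_group",
    "difference_histogram",
    "success_rate",
    "cap_events_per_subject",
]

#: default matching tolerance, ms — the half-range of the difference histogram
DEFAULT_TOLERANCE_MS = 400.0


@dataclass(frozen=True)
class MatchedPair:
    """A reference event paired with a detected event of the same kind.

    ``difference_ms`` is ``(t_reference − t_detected) · 1000``; positive
    means the detector was earlier than the reference.
    """

    reference: GaitEvent
    detected: GaitEvent
    difference_ms: float

    @property
    def kind(self) -> str:
        return self.reference.kind


@dataclass
class MatchResult:
    """Pairing of a detected series against a reference series."""

    pairs: list[MatchedPair]
    missed: list[GaitEvent]  # reference events with no match
    extra: list[GaitEvent]  # detected events with no match

    def pairs_of_kind(self, kind: str) -> list[MatchedPair]:
        return [p for p in self.pairs if p.kind == kind]

    def differences(self, kind: Optional[str] = None) -> list[float]:
        pairs = self.pairs if kind is None else self.pairs_of_kind(kind)
        return [p.difference_ms for p in pairs]


@dataclass(frozen=True)
class TimingSummary:
    """Group-level timing summary across subjects (all values in ms)."""

    amd: float
    md: float
    ci_low: float
    ci_high: float
    n_subjects: int
    subject_amds: tuple[float, ...] = ()
    subject_mds: tuple[float, ...] = ()


@dataclass(frozen=True)
class DifferenceHistogram:
    """Binned timing differences: 80 half-open 10 ms bins over [−400, 400)."""

    edges: np.ndarray
    counts: np.ndarray
    n_out_of_range: int

    @property
    def n_in_range(self) -> int:
        return int(self.counts.sum())


def match_events(
    detected: EventSeries,
    reference: EventSeries,
    tolerance_ms: float = DEFAULT_TOLERANCE_MS,
) -> MatchResult:
    """Pair detected with reference events of the same kind.

    Greedy in temporal order of the reference series: each reference event
    takes the nearest still-unmatched detected event of its kind within
    ``tolerance_ms``. Leftover reference events are classified as missed,
    leftover detected events as extra. Conservation holds per kind:
    ``len(pairs) + len(missed) == len(reference)`` and
    ``len(pairs) + len(extra) == len(detected)``.
    """
    pairs: list[MatchedPair] = []
    missed: list[GaitEvent] = []
    extra: list[GaitEvent] = []
    for kind in (IC, FO):
        refs = reference.of_kind(kind)
        dets = detected.of_kind(kind)
        used = [False] * len(dets)
        for r in refs:
            best_j = -1
            best_dt = math.inf
            for j, d in enumerate(dets):
                if used[j]:
                    continue
                dt = abs(r.time - d.time) * 1000.0
                if dt <= tolerance_ms and dt < best_dt:
                    best_j, best_dt = j, dt
            if best_j >= 0:
                used[best_j] = True
                d = dets[best_j]
                pairs.append(MatchedPair(r, d, (r.time - d.time) * 1000.0))
            else:
                missed.append(r)
        extra.extend(d for j, d in enumerate(dets) if not used[j])
    pairs.sort(key=lambda p: p.reference.time)
    missed.sort(key=lambda e: e.time)
    extra.sort(key=lambda e: e.time)
    return MatchResult(pairs=pairs, missed=missed, extra=extra)


def timing_differences(pairs: Iterable[MatchedPair]) -> list[float]:
    """Signed differences ``t_reference − t_detected`` in ms, one per pair."""
    return [p.difference_ms for p in pairs]


def summarize_subject(differences: Sequence[float]) -> tuple[float, float]:
    """Per-subject summary: ``(AMD, MD)``.

    MD is the mean of the signed differences; AMD the mean of their
    absolute values, so AMD ≥ |MD| always.
    """
    if len(differences) == 0:
        raise ValueError("cannot summarise an empty list of differences")
    arr = np.asarray(differences, dtype=float)
    return float(np.mean(np.abs(arr))), float(np.mean(arr))


def summarize_group(
    subject_mds: Sequence[float], subject_amds: Sequence[float]
) -> TimingSummary:
    """Group summary: unweighted means across subjects + 95% CI on the MD.

    The confidence interval is Student-t based,
    ``MD ± t(0.975, n−1) · SD / sqrt(n)`` over the per-subject mean
    differences; with fewer than two subjects the CI is undefined (NaN).
    """
    if len(subject_mds) != len(subject_amds):
        raise ValueError("subject_mds and subject_amds must have equal length")
    if len(subject_mds) == 0:
        raise ValueError("need at least one subject")
    mds = np.asarray(subject_mds, dtype=float)
    amds = np.asarray(subject_amds, dtype=float)
    n = len(mds)
    md = float(np.mean(mds))
    amd = float(np.mean(amds))
    if n >= 2:
        sd = float(np.std(mds, ddof=1))
        half = float(stats.t.ppf(0.975, n - 1)) * sd / math.sqrt(n)
        ci_low, ci_high = md - half, md + half
    else:
        ci_low = ci_high = math.nan
    return TimingSummary(
        amd=amd,
        md=md,
        ci_low=ci_low,
        ci_high=ci_high,
        n_subjects=n,
        subject_amds=tuple(float(x) for x in amds),
        subject_mds=tuple(float(x) for x in mds),
    )


def difference_histogram(
    differences: Sequence[float],
    low: float = -400.0,
    high: float = 400.0,
    width: float = 10.0,
) -> DifferenceHistogram:
    """Bin timing differences into half-open ``[edge, edge + width)`` bins.

    Exactly ``low`` falls in the first bin; exactly ``high`` is out of
    range. The in-range counts plus the out-of-range count always equal the
    input size.
    """
    arr = np.asarray(differences, dtype=float)
    edges = np.arange(low, high + width, width)
    in_range = (arr >= low) & (arr < high)
    counts, _ = np.histogram(arr[in_range], bins=edges)
    return DifferenceHistogram(
        edges=edges,
        counts=counts,
        n_out_of_range=int(arr.size - in_range.sum()),
    )


def success_rate(n_correct: int, n_reference: int) -> float:
    """Success in detection: ``100 · n_correct / n_reference`` (percent).

    ``n_reference`` must be positive and ``0 ≤ n_correct ≤ n_reference``.
    Report to one decimal, matching the convention of reliability tables.
    """
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    if not (0 <= n_correct <= n_reference):
        raise ValueError("n_correct must be within [0, n_reference]")
    return 100.0 * n_correct / n_reference


def cap_events_per_subject(
    pairs_by_subject: Mapping[str, Sequence[MatchedPair]],
    max_ic: int,
    max_fo: int,
) -> dict[str, list[MatchedPair]]:
    """Keep the first ``max_ic`` IC and ``max_fo`` FO pairs per subject.

    Using the same number of events per subject avoids biasing pooled
    histograms toward subjects who contributed more steps. Subjects with
    fewer events than the cap keep what they have (no padding).
    """
    if max_ic < 0 or max_fo < 0:
        raise ValueError("caps must be >= 0")
    out: dict[str, list[MatchedPair]] = {}
    for subject, pairs in pairs_by_subject.items():
        ordered = sorted(pairs, key=lambda p: p.reference.time)
        kept: list[MatchedPair] = []
        n_ic = n_fo = 0
        for p in ordered:
            if p.kind == IC and n_ic < max_ic:
                kept.append(p)
                n_ic += 1
            elif p.kind == FO and n_fo < max_fo:
                kept.append(p)
                n_fo += 1
        out[subject] = kept
    return out


def plot_histogram(hist: DifferenceHistogram, path, title: str = "") -> None:
    """Save a bar plot of a difference histogram to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 3.5))
    centers = hist.edges[:-1] + np.diff(hist.edges) / 2
    ax.bar(centers, hist.counts, width=np.diff(hist.edges), edgecolor="none")
    ax.set_xlabel("time difference (ms), reference − detected")
    ax.set_ylabel("events")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
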