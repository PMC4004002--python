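"""Event matching, timing statistics, histograms and success rate."""

import math

import numpy as np
import pytest

from gyrogait import (
    EventSeries,
    GaitEvent,
    cap_events_per_subject,
    difference_histogram,
    match_events,
    success_rate,
    summarize_group,
    summarize_subject,
    timing_differences,
)
from gyrogait.evaluation import MatchedPair


def series(times_kinds, source="reference"):
    return EventSeries(
        [GaitEvent(k, None, t) for t, k in times_kinds], source=source
    )


def alternating(start, n_pairs, stride=1.2):
    out = []
    for i in range(n_pairs):
        out.append((start + i * stride, "IC"))
        out.append((start + i * stride + 0.6, "FO"))
    return out


class TestMatchEvents:
    def test_identical_series_all_paired(self):
        ref = series(alternating(1.0, 5))
        det = series(alternating(1.0, 5), source="detected")
        result = match_events(det, ref)
        assert len(result.pairs) == 10
        assert result.missed == [] and result.extra == []
        assert all(p.difference_ms == 0.0 for p in result.pairs)

    def test_one_fo_omitted(self):
        ref = series(alternating(1.0, 5))
        events = alternating(1.0, 5)
        del events[7]  # drop the 4th FO
        det = series(events, source="detected")
        result = match_events(det, ref)
        assert len(result.pairs) == 9
        assert len(result.missed) == 1 and result.missed[0].kind == "FO"
        assert result.extra == []

    def test_far_detection_is_extra(self):
        ref = series([(1.0, "IC")])
        det = series([(1.5, "IC")], source="detected")  # 500 ms away
        result = match_events(det, ref, tolerance_ms=400.0)
        assert result.pairs == []
        assert len(result.missed) == 1 and len(result.extra) == 1

    def test_conservation_per_kind(self):
        rng = np.random.default_rng(12)
        ref = series(alternating(0.5, 8))
        noisy = [
            (t + rng.normal(0.0, 0.3), k) for t, k in alternating(0.5, 8)
        ]
        noisy.append((30.0, "IC"))
        det = series(sorted(noisy), source="detected")
        result = match_events(det, ref)
        for kind in ("IC", "FO"):
            n_pairs = len(result.pairs_of_kind(kind))
            n_missed = sum(e.kind == kind for e in result.missed)
            n_extra = sum(e.kind == kind for e in result.extra)
            assert n_pairs + n_missed == len(ref.of_kind(kind))
            assert n_pairs + n_extra == len(det.of_kind(kind))

    def test_kinds_never_cross_matched(self):
        ref = series([(1.0, "IC")])
        det = series([(1.01, "FO")], source="detected")
        result = match_events(det, ref)
        assert result.pairs == []


class TestTimingDifferences:
    def test_sign_convention(self):
        # detector earlier than reference -> positive difference
        ref = series([(1.0, "IC"), (2.0, "FO")])
        det = series([(0.98, "IC"), (2.048, "FO")], source="detected")
        diffs = timing_differences(match_events(det, ref).pairs)
        assert diffs[0] == pytest.approx(20.0)
        assert diffs[1] == pytest.approx(-48.0)

    def test_shift_property(self):
        ref = series(alternating(1.0, 4))
        base = alternating(1.0, 4)
        for delta_ms in (0.0, 35.0, -80.0):
            det = series(
                [(t + delta_ms / 1000.0, k) for t, k in base], source="detected"
            )
            diffs = timing_differences(match_events(det, ref).pairs)
            assert np.allclose(diffs, -delta_ms)


class TestSummaries:
    @pytest.mark.parametrize(
        "diffs, amd, md",
        [
            ([10.0, -10.0], 10.0, 0.0),
            ([20.0, 20.0, 20.0], 20.0, 20.0),
            ([-35.0, -15.0, -55.0], 35.0, -35.0),
        ],
    )
    def test_subject_summary(self, diffs, amd, md):
        got_amd, got_md = summarize_subject(diffs)
        assert got_amd == pytest.approx(amd)
        assert got_md == pytest.approx(md)
        assert got_amd >= abs(got_md)

    def test_empty_subject_rejected(self):
        with pytest.raises(ValueError):
            summarize_subject([])

    def test_group_zero_variance(self):
        s = summarize_group([7.0, 7.0, 7.0], [9.0, 9.0, 9.0])
        assert s.md == 7.0 and s.amd == 9.0
        assert s.ci_low == pytest.approx(7.0) and s.ci_high == pytest.approx(7.0)

    def test_group_two_subjects_t_interval(self):
        # closed form: md 5, sd 7.0711, t(0.975, 1) = 12.7062
        # half-width = 12.7062 * 7.0711 / sqrt(2) = 63.531
        s = summarize_group([0.0, 10.0], [0.0, 10.0])
        assert s.md == pytest.approx(5.0)
        half = 12.706204736 * math.sqrt(50.0) / math.sqrt(2.0)
        assert s.ci_low == pytest.approx(5.0 - half, rel=1e-6)
        assert s.ci_high == pytest.approx(5.0 + half, rel=1e-6)

    def test_group_recovers_injected_offsets(self):
        offsets = [-30.0, -10.0, 0.0, 5.0, 12.0, 20.0, 33.0]
        mds, amds = [], []
        for off in offsets:
            amd, md = summarize_subject([off] * 6)
            mds.append(md)
            amds.append(amd)
        s = summarize_group(mds, amds)
        assert s.md == pytest.approx(float(np.mean(offsets)))
        assert s.ci_low <= s.md <= s.ci_high

    def test_single_subject_ci_undefined(self):
        s = summarize_group([3.0], [3.0])
        assert math.isnan(s.ci_low) and math.isnan(s.ci_high)


class TestHistogram:
    def test_small_positive_values_share_a_bin(self):
        h = difference_histogram([0.0, 5.0, 9.0])
        bin_of_zero = int(np.searchsorted(h.edges, 0.0, side="right") - 1)
        assert h.counts[bin_of_zero] == 3
        assert h.counts.sum() == 3 and h.n_out_of_range == 0

    def test_boundary_rules(self):
        h = difference_histogram([-400.0, 400.0])
        assert h.counts[0] == 1  # exactly -400 in the first bin
        assert h.n_out_of_range == 1  # exactly +400 out of range
        assert len(h.counts) == 80

    def test_empty_input(self):
        h = difference_histogram([])
        assert h.counts.sum() == 0 and h.n_out_of_range == 0

    def test_count_conservation(self):
        rng = np.random.default_rng(5)
        diffs = rng.normal(0.0, 300.0, 500)
        h = difference_histogram(diffs)
        assert h.n_in_range + h.n_out_of_range == 500


class TestSuccessRate:
    @pytest.mark.parametrize(
        "correct, total, expected",
        [(42, 44, 95.5), (54, 58, 93.1), (0, 10, 0.0), (10, 10, 100.0)],
    )
    def test_values(self, correct, total, expected):
        assert round(success_rate(correct, total), 1) == expected

    def test_monotone_in_n_correct(self):
        rates = [success_rate(k, 20) for k in range(21)]
        assert all(b >= a for a, b in zip(rates, rates[1:]))
        assert all(0.0 <= r <= 100.0 for r in rates)

    @pytest.mark.parametrize("correct, total", [(1, 0), (-1, 5), (6, 5)])
    def test_invalid_counts(self, correct, total):
        with pytest.raises(ValueError):
            success_rate(correct, total)


def _pairs(n_ic, n_fo, start=0.0):
    out = []
    t = start
    for _ in range(max(n_ic, n_fo)):
        if n_ic > 0:
            ref = GaitEvent("IC", None, t)
            out.append(MatchedPair(ref, GaitEvent("IC", None, t), 0.0))
            n_ic -= 1
        t += 0.6
        if n_fo > 0:
            ref = GaitEvent("FO", None, t)
            out.append(MatchedPair(ref, GaitEvent("FO", None, t), 0.0))
            n_fo -= 1
        t += 0.6
    return out


class TestCapping:
    def test_six_subjects_capped_to_24_ic(self):
        by_subject = {f"s{i}": _pairs(5, 4) for i in range(6)}
        capped = cap_events_per_subject(by_subject, max_ic=4, max_fo=3)
        n_ic = sum(sum(p.kind == "IC" for p in v) for v in capped.values())
        n_fo = sum(sum(p.kind == "FO" for p in v) for v in capped.values())
        assert n_ic == 24 and n_fo == 18

    def test_short_subject_not_padded(self):
        capped = cap_events_per_subject({"s": _pairs(2, 2)}, max_ic=4, max_fo=3)
        assert sum(p.kind == "IC" for p in capped["s"]) == 2

    def test_zero_caps_empty(self):
        capped = cap_events_per_subject({"s": _pairs(3, 3)}, max_ic=0, max_fo=0)
        assert capped["s"] == []

    def test_keeps_earliest(self):
        pairs = _pairs(5, 0)
        capped = cap_events_per_subject({"s": pairs}, max_ic=2, max_fo=0)
        kept_times = [p.reference.time for p in capped["s"]]
        assert kept_times == sorted(p.reference.time for p in pairs)[:2]
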