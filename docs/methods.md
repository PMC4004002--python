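# Methods

## Detection rules

The detector operates on a single channel: sagittal shank angular
velocity, deg/s, positive in the direction of swing-phase rotation,
uniformly sampled (default 125 Hz). The sensor's electrical null output is
not zero; `remove_null_offset` subtracts the mean of a quiet-standing
interval before detection.

The rules are evaluated strictly sample by sample:

* **Zero crossings.** Ascending (AZ) at the first `n` with
  `g(n−1) ≤ 0 < g(n)`; descending (DZ) at the first `n` with
  `g(n−1) > 0 ≥ g(n)`. The half-open, mirror-symmetric conventions make
  each crossing a unique sample and behave correctly on an exactly-zero
  baseline (relevant for noise-free synthetic signals). The sample before
  the start of a signal is taken as 0, so a signal that begins positive
  opens a wave at its first sample.
* **Swing qualification.** Within a positive wave (AZ to DZ) the signal
  must stay at or above `swing_threshold` (+60 deg/s) for at least
  `swing_min_samples` (5) *consecutive* samples — a sustained interval,
  not a cumulative count. Unqualified waves are discarded and the search
  resumes after them; this is what keeps the detector silent through
  standing-still weight shifts and shuffles.
* **IC.** The first `n` after the DZ with `g(n) < 0`, `g(n) < g(n−1)` and
  `g(n) ≤ g(n+1)`. On a flat-bottomed dip the first sample of the plateau
  wins. If the signal ends mid-descent the partial cycle is dropped.
* **Waiting time.** The FO search starts
  `round(wait_time_ms · fs / 1000)` samples after IC (default 200 ms →
  25 samples at 125 Hz). The interval exists to skip loading-response
  oscillations, which are strongest just after foot impact; it must be
  shorter than the stance phase. 200 ms satisfies both constraints for
  ordinary cadences and is configurable.
* **FO.** The first candidate `n` at or after the search start with
  (a) `g(n) ≤ fo_threshold` (−60 deg/s) and (b) `g(n)` the **strict**
  minimum of the window `[n − 10, n + 15]` (26 samples total; clipped at
  signal ends, so end-of-trial events are not discarded). A tied value
  anywhere else in the window disqualifies the candidate. Strictness is
  deliberate: an area of equal-depth local minima — which quantized real
  signals do produce — then contains *no* valid FO, reproducing the
  observed missed-FO failure, whereas any first-tie-wins rule would always
  accept the first sample attaining the regional minimum.
* **Preemption.** During the FO search a parallel swing tracker runs from
  IC+1. If `preempt_fo_on_new_swing` is on (default), the search aborts at
  the first index `n` at or after the search start where, after
  incorporating `g(n)`, the tracker is inside a qualified wave; the FO is
  recorded as missed and the wave is processed as the next swing, so its
  following minimum is emitted as an IC (possibly producing consecutive
  ICs). The tracker is consulted before the FO condition at the same
  index; the two can never both hold at one sample because the thresholds
  have opposite signs. With preemption off the search continues until an
  FO is found or the signal ends.

The 26-sample window corresponds to 208 ms at 125 Hz; the sample count is
treated as authoritative and "200 ms" as its rounded description.

### Streaming

`StreamingDetector` runs the identical decision sequence incrementally.
An FO at index `n` is decided when sample `n + 15` arrives (worst-case
latency 15 samples = 120 ms at 125 Hz); an IC needs one sample of
lookahead. `close()` resolves candidates whose windows are clipped by the
end of the stream. Batch/stream equality is exact and is enforced by tests
against both the batch implementation and an independent brute-force
oracle.

## Synthetic signal generator

The simulator emulates signal-level morphology only — it is not a
biomechanical model, and passing tests on it says nothing about sensor
placement, soft-tissue artefact, drift or pathological gait. One stride
(default cadence 50 strides/min → 1.2 s) is a concatenation of
raised-cosine (sin²) lobes: swing 32% of the stride, IC dip 10%, stance
45%, FO dip 13%. Dip segments have even length so the extremum is a
single sample; the truth IC/FO indices are the dip minima of the
noiseless template.

Defaults (deg/s unless noted): swing peak 350 on level ground, 180 for
stair ascent (the swing wave is visibly reduced when climbing), 300 for
descent; IC and FO dip depths −150; stance level −25; stance oscillations
8 Hz, amplitude 40, decaying exponentially (τ = 150 ms) from stance onset
— emulating loading-response artefacts, which die out during stance; for
stair ascent a +50 positive stance excursion (the shank briefly rotates
forward during pull-up; sub-threshold by default, and raising it above
+60 with sufficient width reproduces the FO-mislabelled-as-IC failure).
Measurement noise is additive white Gaussian, default SD 10. Standing
still is band-limited noise rescaled to max |g| = 40, below both
thresholds by construction. All amplitudes are plausible magnitudes for
walking, chosen once; they are not claims about any particular recorded
dataset.

A single `numpy.random.Generator` drives all randomness: identical seeds
give bit-identical signals.

## Evaluation protocol

Detected events are matched to reference events of the same kind by a
greedy in-order rule: each reference event takes the nearest unmatched
detection within ±400 ms (the half-range of the difference histogram);
leftovers are missed (reference) or extra (detected). Differences are
`t_reference − t_detected` in ms — positive when the detector fires
early. Per subject, MD = mean and AMD = mean absolute difference; across
subjects the unweighted means are reported with a Student-t 95% CI
(`MD ± t₀.₉₇₅,ₙ₋₁ · SD/√n`), appropriate for cohorts of 6–7. Histograms
use 80 half-open 10 ms bins over [−400, 400); exactly −400 falls in the
first bin, exactly +400 is out of range. Success in detection is
100 · (events correctly detected) / (reference events). For pooled
histograms, per-subject event counts can be capped (first k IC, first m
FO) to avoid weighting subjects unequally.

## Benchmark cohort

`run_stair_cohort` (used by `scripts/acceptance.py` and the acceptance
tests) simulates 7 subjects × {8 ascent strides, 8 descent strides} with
noise SD 10 and oscillation amplitude 40, 2 s of standing before and
after. Subject k is seeded with `SeedSequence(base_seed + k)`; the two
activities use spawned child streams. These problem sizes keep the full
benchmark under a few seconds while providing 224 truth events. Typical
results: group AMD ≈ 30–42 ms for IC (the first-local-minimum rule is
noise-sensitive on the dip's shallow entry slope, biasing IC slightly
early), ≈ 5–30 ms for FO, success ≈ 93–96% — the shortfall from 100% is
dominated by stance oscillations occasionally passing the FO rules early
enough to fall outside the matching tolerance.

## Numerical choices and edge cases

* Durations are converted to samples as `round(ms · fs / 1000)`.
* Event time = `index / fs + t0`, 0-based indexing.
* Empty signals yield empty series; an FO search that reaches the end of
  the signal without success ends detection (batch) or is resolved with a
  clipped window at `close()` (streaming).
* With `wait_time_ms = 0` the IC sample itself is an FO candidate.
* Ties: IC takes the first sample of a minimum plateau; FO accepts no
  ties at all (see above).
* CSV timestamps are validated against the declared sampling rate to
  1 µs; file writes are atomic so failed commands leave no partial output.

## Known limitations

* The detector processes one axis from one sensor; no fusion, drift or
  temperature compensation.
* The matching rule between detected and reference events (greedy,
  ±400 ms) is an evaluation-protocol choice; published studies rarely
  state theirs, so absolute comparability of missed/extra counts across
  implementations is limited.
* Simulator realism bounds what the benchmark can demonstrate: real
  stair-walking signals show subject-specific irregularity (multi-bump
  stance, variable dip shapes) that the template family cannot produce;
  the regression fixtures for the three documented failure modes are
  constructed, not sampled.
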