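"""Synthetic shank angular-velocity signals with ground-truth events.

The generator emulates the signal-level morphology of sagittal shank
angular velocity during walking, not the underlying joint kinematics. One
gait cycle is built from piecewise raised-cosine (sin^2) lobes:

* a positive swing lobe (peak ``swing_peak``, clearly reduced for stair
  ascent, where the shank rotates less during swing);
* a negative initial-contact dip whose minimum is the truth IC;
* a stance plateau at a small negative level with exponentially decaying
  zero-phase oscillations (emulating the loading-response artefacts seen
  just after foot impact) and, for stair ascent only, a positive excursion
  (the shank briefly rotates forward during the pull-up phase);
* a terminal negative foot-off dip whose minimum is the truth FO.

Standing-still segments are band-limited noise rescaled so that the
absolute signal never reaches either detection threshold, which is what
keeps the detector quiescent between walks. All randomness flows through a
single :class:`numpy.random.Generator`, so a fixed seed reproduces the
signal bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .events import FO, IC, EventSeries, GaitEvent
from .signal import GyroSignal

__all__ = ["StrideParams", "SimulatedWalk", "simulate_stride", "simulate_walk"]

#: default swing-lobe peak per terrain (deg/s)
TERRAIN_SWING_PEAK = {"level": 350.0, "stair_up": 180.0, "stair_down": 300.0}

#: per-sample segment labels, after the walking-circuit terrain codes
SEGMENT_LABELS = {"level": "LW", "stair_up": "SU", "stair_down": "SD", "standing": "SS"}

# fractions of the stride spent in each sub-phase (swing, IC dip, stance, FO dip)
_FRACTIONS = (0.32, 0.10, 0.45, 0.13)


@dataclass(frozen=True)
class StrideParams:
    """Generation parameters for one walking condition.

    Amplitudes are in deg/s; the dip depths are negative. ``swing_peak``
    and ``stance_positive_excursion`` default per terrain (``None`` means
    "use the terrain default": 350/180/300 deg/s swing peak for
    level/stair_up/stair_down and a +50 deg/s stance excursion for
    stair_up only).
    """

    terrain: str = "level"
    cadence: float = 50.0  # strides per minute
    swing_peak: Optional[float] = None
    ic_dip_depth: float = -150.0
    fo_dip_depth: float = -150.0
    stance_level: float = -25.0
    stance_oscillation_amp: float = 40.0
    stance_oscillation_freq: float = 8.0  # Hz
    stance_oscillation_decay_ms: float = 150.0
    stance_positive_excursion: Optional[float] = None
    noise_sd: float = 10.0
    wiggle_amp: float = 40.0  # standing-still max |g|
    fs: float = 125.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.terrain not in TERRAIN_SWING_PEAK:
            raise ValueError(f"unknown terrain {self.terrain!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.cadence <= 0:
            raise ValueError("cadence must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if not (self.ic_dip_depth < 0 and self.fo_dip_depth < 0):
            raise ValueError("dip depths must be negative")

    @property
    def swing_peak_value(self) -> float:
        if self.swing_peak is not None:
            return self.swing_peak
        return TERRAIN_SWING_PEAK[self.terrain]

    @property
    def stance_excursion_value(self) -> float:
        if self.stance_positive_excursion is not None:
            return self.stance_positive_excursion
        return 50.0 if self.terrain == "stair_up" else 0.0

    def replace(self, **changes) -> "StrideParams":
        return replace(self, **changes)


@dataclass
class SimulatedWalk:
    """A synthetic walk: signal, ground truth and provenance."""

    signal: GyroSignal
    truth: EventSeries
    params: StrideParams
    labels: np.ndarray = field(default_factory=lambda: np.array([], dtype="<U2"))


def _lobe(amplitude: float, n: int) -> np.ndarray:
    """Raised-cosine lobe of ``n`` samples, zero at both ends.

    For even ``n`` the extremum is attained at the single sample ``n // 2``,
    which keeps dip minima unique (important because a tied minimum is not a
    valid foot-off candidate).
    """
    k = np.arange(n)
    return amplitude * np.sin(np.pi * k / n) ** 2


def _stance(params: StrideParams, n: int) -> np.ndarray:
    """Stance-phase waveform: shallow negative plateau + decaying
    oscillations (+ positive excursion on stair ascent)."""
    ramp_len = max(2, n // 8)
    profile = np.ones(n)
    ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(ramp_len) / ramp_len))
    profile[:ramp_len] = ramp
    profile[n - ramp_len :] = ramp[::-1]
    out = params.stance_level * profile
    if params.stance_oscillation_amp > 0:
        t = np.arange(n) / params.fs
        tau = params.stance_oscillation_decay_ms / 1000.0
        decay = np.exp(-t / tau) if tau > 0 else np.ones(n)
        osc = (
            params.stance_oscillation_amp
            * decay
            * np.sin(2.0 * np.pi * params.stance_oscillation_freq * t)
        )
        out += osc * profile
    excursion = params.stance_excursion_value
    if excursion:
        width = max(4, int(round(0.4 * n)))
        start = (n - width) // 2
        out[start : start + width] += _lobe(excursion, width)
    return out


def _segment_lengths(params: StrideParams) -> tuple[int, int, int, int]:
    n_total = int(round(params.fs * 60.0 / params.cadence))
    n_swing = int(round(_FRACTIONS[0] * n_total))
    n_ic = int(round(_FRACTIONS[1] * n_total))
    n_fo = int(round(_FRACTIONS[3] * n_total))
    # even dip lengths give a unique extremum sample at n // 2
    n_ic += n_ic % 2
    n_fo += n_fo % 2
    n_stance = n_total - n_swing - n_ic - n_fo
    if n_stance < 8:
        raise ValueError(
            f"cadence {params.cadence} strides/min leaves no room for a "
            f"stance phase at fs={params.fs}"
        )
    return n_swing, n_ic, n_stance, n_fo


def simulate_stride(
    params: StrideParams, rng: np.random.Generator
) -> tuple[np.ndarray, int, int]:
    """Generate one gait cycle.

    Returns ``(waveform, ic_index, fo_index)`` with the truth indices at the
    dip minima of the noiseless template; Gaussian noise with standard
    deviation ``params.noise_sd`` is added on top.
    """
    n_swing, n_ic, n_stance, n_fo = _segment_lengths(params)
    wave = np.concatenate(
        [
            _lobe(params.swing_peak_value, n_swing),
            _lobe(params.ic_dip_depth, n_ic),
            _stance(params, n_stance),
            _lobe(params.fo_dip_depth, n_fo),
        ]
    )
    ic_index = n_swing + n_ic // 2
    fo_index = n_swing + n_ic + n_stance + n_fo // 2
    if params.noise_sd > 0:
        wave = wave + rng.normal(0.0, params.noise_sd, wave.size)
    return wave, ic_index, fo_index


def _standing(n: int, params: StrideParams, rng: np.random.Generator) -> np.ndarray:
    """Standing-still wiggle: band-limited noise with max |g| = wiggle_amp."""
    if n <= 0:
        return np.zeros(0)
    if params.wiggle_amp <= 0:
        return np.zeros(n)
    win = max(3, int(round(0.2 * params.fs)))
    kernel = np.hanning(win)
    kernel /= kernel.sum()
    raw = rng.normal(size=n + win)
    smooth = np.convolve(raw, kernel, mode="same")[:n]
    peak = np.max(np.abs(smooth))
    if peak > 0:
        smooth *= params.wiggle_amp / peak
    return smooth


def simulate_walk(
    n_strides: int,
    params: StrideParams | None = None,
    standing_pre_s: float = 0.0,
    standing_post_s: float = 0.0,
    *,
    pause_after: Optional[int] = None,
    pause_s: float = 0.0,
    rng: Optional[np.random.Generator] = None,
    t0: float = 0.0,
) -> SimulatedWalk:
    """Generate a full walk with optional standing-still segments.

    Parameters
    ----------
    n_strides : int
        Number of gait cycles (each contributes one truth IC and one FO).
    params : StrideParams, optional
        Generation parameters; defaults to level walking.
    standing_pre_s, standing_post_s : float
        Durations (s) of standing-still wiggle before and after the strides.
    pause_after : int, optional
        If given, insert a standing pause of ``pause_s`` seconds after this
        many strides (1-based count), emulating stopping mid-circuit.
    rng : numpy.random.Generator, optional
        Randomness source; defaults to ``default_rng(params.seed)``.
    """
    if n_strides < 0:
        raise ValueError("n_strides must be >= 0")
    params = params or StrideParams()
    if rng is None:
        rng = np.random.default_rng(params.seed)
    stride_label = SEGMENT_LABELS[params.terrain]

    chunks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    truth: list[tuple[str, int]] = []
    offset = 0

    def add_standing(duration_s: float) -> None:
        nonlocal offset
        n = int(round(duration_s * params.fs))
        seg = _standing(n, params, rng)
        chunks.append(seg)
        labels.append(np.full(seg.size, SEGMENT_LABELS["standing"], dtype="<U2"))
        offset += seg.size

    add_standing(standing_pre_s)
    for k in range(n_strides):
        wave, ic, fo = simulate_stride(params, rng)
        chunks.append(wave)
        labels.append(np.full(wave.size, stride_label, dtype="<U2"))
        truth.append((IC, offset + ic))
        truth.append((FO, offset + fo))
        offset += wave.size
        if pause_after is not None and k + 1 == pause_after and k + 1 < n_strides:
            add_standing(pause_s)
    add_standing(standing_post_s)

    samples = np.concatenate(chunks) if chunks else np.zeros(0)
    signal = GyroSignal(samples, fs=params.fs, t0=t0)
    events = [
        GaitEvent(kind, idx, signal.time_of(idx)) for kind, idx in truth
    ]
    return SimulatedWalk(
        signal=signal,
        truth=EventSeries(events, source="truth"),
        params=params,
        labels=np.concatenate(labels) if labels else np.array([], dtype="<U2"),
    )
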