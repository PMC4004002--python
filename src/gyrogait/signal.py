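"""Angular-velocity signal container and baseline (null-output) correction.

The sensor of interest is a single-axis rate gyroscope strapped to the shank,
measuring sagittal-plane angular velocity in deg/s. By convention positive
velocity is the forward (counter-clockwise) rotation of the shank seen during
the swing phase of gait; stance-phase rotation is negative. The electrical
null output of the sensor circuit is not exactly zero, so a baseline measured
during quiet standing is subtracted before event detection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GyroSignal", "remove_null_offset"]


@dataclass(frozen=True)
class GyroSignal:
    """A uniformly sampled angular-velocity series.

    Parameters
    ----------
    samples : array-like of float
        Angular velocity per sample, deg/s. Must be finite.
    fs : float
        Sampling frequency in Hz; must be positive. The recordings this
        package targets are sampled at 125 Hz.
    t0 : float, optional
        Time of the first sample in seconds (default 0). Sample ``n`` is at
        time ``t0 + n / fs`` (0-based).
    """

    samples: np.ndarray
    fs: float = 125.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.asarray(self.samples, dtype=float)
        if samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if not np.all(np.isfinite(samples)):
            raise ValueError("samples must be finite")
        if not (self.fs > 0):
            raise ValueError(f"fs must be positive, got {self.fs}")
        object.__setattr__(self, "samples", samples)

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def times(self) -> np.ndarray:
        """Time of every sample, seconds."""
        return self.t0 + np.arange(len(self.samples)) / self.fs

    def time_of(self, index: int) -> float:
        """Time of sample ``index`` in seconds."""
        return self.t0 + index / self.fs


def remove_null_offset(signal: GyroSignal, baseline: tuple[int, int]) -> GyroSignal:
    """Subtract the sensor's null output, estimated from a quiet interval.

    Parameters
    ----------
    signal : GyroSignal
    baseline : (start, stop)
        Half-open sample-index interval ``[start, stop)`` over which the
        mean is taken; typically a quiet-standing stretch recorded before
        the walk. Must be non-empty and within the signal.

    Returns
    -------
    GyroSignal
        Signal minus the arithmetic mean of the baseline samples; ``fs``
        and ``t0`` are unchanged.
    """
    start, stop = baseline
    n = len(signal)
    if not (0 <= start < stop <= n):
        raise ValueError(
            f"baseline interval [{start}, {stop}) is empty or outside the "
            f"signal of length {n}"
        )
    offset = float(np.mean(signal.samples[start:stop]))
    return GyroSignal(signal.samples - offset, fs=signal.fs, t0=signal.t0)
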