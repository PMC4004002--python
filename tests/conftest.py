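"""Shared fixtures and signal builders for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from gyrogait import DetectorConfig, GyroSignal, StrideParams, simulate_walk

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")

FS = 125.0


@pytest.fixture
def cfg() -> DetectorConfig:
    return DetectorConfig()


def make_signal(values, fs: float = FS, t0: float = 0.0) -> GyroSignal:
    return GyroSignal(np.asarray(values, dtype=float), fs=fs, t0=t0)


def lobe(amplitude: float, n: int) -> np.ndarray:
    """Raised-cosine lobe, zero at both ends, extremum at n // 2 for even n."""
    k = np.arange(n)
    return amplitude * np.sin(np.pi * k / n) ** 2


def stride_like(
    swing_peak: float = 300.0,
    n_swing: int = 40,
    ic_depth: float = -150.0,
    n_ic: int = 14,
    stance_level: float = -30.0,
    n_stance: int = 40,
    fo_depth: float = -150.0,
    n_fo: int = 14,
    lead: int = 30,
    tail: int = 10,
) -> np.ndarray:
    """A crafted one-stride signal with controllable amplitudes/durations."""
    return np.concatenate(
        [
            np.zeros(lead),
            lobe(swing_peak, n_swing),
            lobe(ic_depth, n_ic),
            np.full(n_stance, stance_level),
            lobe(fo_depth, n_fo),
            np.zeros(tail),
        ]
    )


def random_signal(rng: np.random.Generator) -> np.ndarray:
    """A randomized short signal exercising many detector paths.

    A mix of pure noise, simulated walks (all terrains, varied noise and
    oscillation amplitudes including above-threshold ones) and sequences of
    random-amplitude lobes.
    """
    flavour = rng.integers(0, 3)
    if flavour == 0:
        n = int(rng.integers(150, 500))
        return rng.normal(0.0, rng.uniform(5.0, 90.0), n)
    if flavour == 1:
        params = StrideParams(
            terrain=("level", "stair_up", "stair_down")[rng.integers(0, 3)],
            noise_sd=float(rng.uniform(0.0, 25.0)),
            stance_oscillation_amp=float(rng.uniform(0.0, 90.0)),
            stance_oscillation_decay_ms=float(rng.uniform(50.0, 2000.0)),
            cadence=float(rng.uniform(35.0, 70.0)),
        )
        walk = simulate_walk(int(rng.integers(1, 4)), params, 0.5, 0.5, rng=rng)
        return walk.signal.samples
    chunks = [np.zeros(int(rng.integers(0, 30)))]
    for _ in range(int(rng.integers(2, 10))):
        amp = float(rng.uniform(-350.0, 350.0))
        width = int(rng.integers(3, 45))
        chunks.append(lobe(amp, width))
        chunks.append(np.full(int(rng.integers(0, 20)), rng.uniform(-70.0, 40.0)))
    sig = np.concatenate(chunks)
    if rng.random() < 0.5:
        sig = sig + rng.normal(0.0, rng.uniform(1.0, 15.0), sig.size)
    return sig
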