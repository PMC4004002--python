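"""Detector configuration: every tunable of the rule-based algorithm.

Defaults are the empirically determined values of the original algorithm:
a swing wave must exceed +60 deg/s for at least 5 consecutive samples
(40 ms at 125 Hz); a foot-off candidate must reach −60 deg/s and be the
unique minimum of a 26-sample window split as 10 samples behind, the
candidate itself, and 15 samples of lookahead; the search for foot off
starts a configurable waiting time (default 200 ms) after initial contact
to skip loading-response oscillations.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

__all__ = ["DetectorConfig"]

_BOOL_TRUE = {"1", "true", "yes", "on"}
_BOOL_FALSE = {"0", "false", "no", "off"}


@dataclass(frozen=True)
class DetectorConfig:
    """Thresholds, durations and window sizes of the detection rules.

    Attributes
    ----------
    swing_threshold : float
        Angular velocity (deg/s) the swing wave must exceed. Default +60.
    swing_min_samples : int
        Consecutive samples the signal must stay at or above
        ``swing_threshold`` for the wave to count as a swing. Default 5.
    fo_threshold : float
        Level (deg/s) a foot-off candidate must reach (at or below).
        Default −60.
    fo_window : int
        Total width (samples) of the minimum window for foot off.
        Default 26.
    fo_lookahead : int
        Samples of the window ahead of the candidate. Default 15; the
        remaining ``fo_window − 1 − fo_lookahead`` samples lie behind.
    wait_time_ms : float
        Waiting time after initial contact before the foot-off search
        starts, in ms. Default 200.
    preempt_fo_on_new_swing : bool
        If true (default), a qualifying swing wave occurring during the
        foot-off search aborts it (the foot off is missed and the new
        wave is processed as the next swing). If false, the search
        continues until a foot off is found or the signal ends.
    """

    swing_threshold: float = 60.0
    swing_min_samples: int = 5
    fo_threshold: float = -60.0
    fo_window: int = 26
    fo_lookahead: int = 15
    wait_time_ms: float = 200.0
    preempt_fo_on_new_swing: bool = True

    def __post_init__(self) -> None:
        if not (self.swing_threshold > 0 > self.fo_threshold):
            raise ValueError(
                "swing_threshold must be positive and fo_threshold negative; "
                f"got {self.swing_threshold} and {self.fo_threshold}"
            )
        if self.swing_min_samples < 1:
            raise ValueError("swing_min_samples must be >= 1")
        if self.fo_lookahead < 0:
            raise ValueError("fo_lookahead must be >= 0")
        if self.fo_window < self.fo_lookahead + 1:
            raise ValueError("fo_window must be >= fo_lookahead + 1")
        if self.wait_time_ms < 0:
            raise ValueError("wait_time_ms must be >= 0")

    @property
    def fo_behind(self) -> int:
        """Samples of the foot-off window behind the candidate."""
        return self.fo_window - 1 - self.fo_lookahead

    def wait_samples(self, fs: float) -> int:
        """Waiting time converted to samples at rate ``fs``: round(ms*fs/1000)."""
        return int(round(self.wait_time_ms * fs / 1000.0))

    def replace(self, **changes) -> "DetectorConfig":
        """Return a copy with the given fields changed."""
        return dataclasses.replace(self, **changes)

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorConfig":
        """Load from a flat ``key = value`` text file.

        Lines starting with ``#`` and blank lines are ignored; keys must be
        DetectorConfig field names.
        """
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
            key, _, val = line.partition("=")
            key, val = key.strip(), val.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown config key {key!r}")
            values[key] = _parse_value(key, val, lineno, path)
        return cls(**values)

    def to_file(self, path: str | Path) -> None:
        """Write as a flat ``key = value`` text file."""
        lines = [
            f"{f.name} = {getattr(self, f.name)}" for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def _parse_value(key: str, val: str, lineno: int, path) -> float | int | bool:
    if key == "preempt_fo_on_new_swing":
        low = val.lower()
        if low in _BOOL_TRUE:
            return True
        if low in _BOOL_FALSE:
            return False
        raise ValueError(f"{path}:{lineno}: expected a boolean for {key}, got {val!r}")
    if key in ("swing_min_samples", "fo_window", "fo_lookahead"):
        try:
            return int(val)
        except ValueError:
            raise ValueError(
                f"{path}:{lineno}: expected an integer for {key}, got {val!r}"
            ) from None
    try:
        return float(val)
    except ValueError:
        raise ValueError(
            f"{path}:{lineno}: expected a number for {key}, got {val!r}"
        ) from None
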