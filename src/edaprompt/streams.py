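"""Electrodermal-activity stream container and the E4-export-style CSV dialect.

An :class:`EdaStream` is the unit of signal I/O throughout the package: an
absolute POSIX start time, a sampling rate (4 Hz for the Empatica E4's EDA
channel), and a nonnegative skin-conductance series in microsiemens (µS).

The on-disk dialect mirrors the wrist-device vendor's per-channel export:

* line 1 — POSIX start timestamp (seconds),
* line 2 — sampling rate in Hz,
* lines 3+ — one conductance sample per line, six decimal places.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = ["EdaStream", "EdaCsvError", "read_e4_csv", "write_e4_csv"]

#: Default EDA sampling rate of the wrist device, in Hz.
DEFAULT_SAMPLE_RATE_HZ = 4.0


class EdaCsvError(ValueError):
    """Raised when an E4-style CSV file cannot be parsed; names the line."""


@dataclass(frozen=True)
class EdaStream:
    """A uniformly sampled skin-conductance series.

    Parameters
    ----------
    start_time : float
        Absolute POSIX timestamp of the first sample, in seconds.
    sample_rate_hz : float
        Samples per second; must be positive. The E4 EDA channel runs at 4 Hz.
    samples : numpy.ndarray
        Conductance values in µS; all nonnegative, length >= 1.
    """

    start_time: float
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ
    samples: np.ndarray = field(default_factory=lambda: np.zeros(1))

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sample_rate_hz <= 0:
            raise ValueError(f"sample_rate_hz must be > 0, got {self.sample_rate_hz}")
        if self.samples.ndim != 1 or self.samples.size < 1:
            raise ValueError("samples must be a 1-d array of length >= 1")
        if np.any(self.samples < 0):
            raise ValueError("EDA samples must be >= 0 µS")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EDA samples must be finite")

    def __len__(self) -> int:
        return int(self.samples.size)

    @property
    def duration_s(self) -> float:
        """Stream duration in seconds (= n samples / rate)."""
        return len(self) / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        """Sample times relative to the stream start, in seconds."""
        return np.arange(len(self)) / self.sample_rate_hz

    @property
    def abs_times(self) -> np.ndarray:
        """Absolute POSIX sample times, in seconds."""
        return self.start_time + self.times_s

    def with_samples(self, samples: np.ndarray) -> "EdaStream":
        """Return a copy of this stream carrying ``samples`` instead."""
        return replace(self, samples=np.asarray(samples, dtype=float))


def write_e4_csv(stream: EdaStream, path: str | Path) -> None:
    """Write ``stream`` to ``path`` in the E4-export-style dialect.

    Values are rendered with six decimal places, which together with
    :func:`read_e4_csv` makes the round trip lossless to 1e-6 µS.
    """
    path = Path(path)
    lines = [f"{stream.start_time:.6f}", f"{stream.sample_rate_hz:.6f}"]
    lines.extend(f"{v:.6f}" for v in stream.samples)
    path.write_text("\n".join(lines) + "\n")


def read_e4_csv(path: str | Path) -> EdaStream:
    """Parse an E4-export-style CSV file back into an :class:`EdaStream`.

    Raises
    ------
    EdaCsvError
        On a malformed header, a nonpositive sample rate, or a nonnumeric
        sample row; the message names the offending line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such EDA file: {path}")
    raw = path.read_text().splitlines()
    if len(raw) < 3:
        raise EdaCsvError(
            f"{path}: expected at least 3 lines (start time, rate, samples), got {len(raw)}"
        )
    try:
        start_time = float(raw[0])
    except ValueError:
        raise EdaCsvError(f"{path}: line 1: start timestamp {raw[0]!r} is not numeric") from None
    try:
        rate = float(raw[1])
    except ValueError:
        raise EdaCsvError(f"{path}: line 2: sample rate {raw[1]!r} is not numeric") from None
    if rate <= 0:
        raise EdaCsvError(f"{path}: line 2: sample rate must be > 0, got {raw[1]!r}")
    values = np.empty(len(raw) - 2)
    for i, row in enumerate(raw[2:], start=3):
        try:
            values[i - 3] = float(row)
        except ValueError:
            raise EdaCsvError(f"{path}: line {i}: sample {row!r} is not numeric") from None
    return EdaStream(start_time=start_time, sample_rate_hz=rate, samples=values)
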