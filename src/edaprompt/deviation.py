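"""Baseline calibration and the streaming EDA deviation-trigger algorithm.

A member's baseline is the mean skin conductance over a 3-minute calibration
window recorded at study orientation. During the study, smoothed EDA is
compared against ``baseline × (1 + threshold_fraction)``; a trigger fires
once the signal has stayed at or above that level for ``sustain_s``
continuous seconds, subject to a refractory period, study-hour gating, and a
daily cap of deviation notifications (four per day by default, matching the
random-prompt load).

The operative threshold defaults to a 20% rise over baseline — the stricter
end of the 15–20% range used for 'meaningful' sympathetic arousal — so that
single noise transients do not page the participant.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from datetime import date, datetime
from typing import Iterable, Sequence

import numpy as np

from .streams import EdaStream

__all__ = [
    "Baseline",
    "DeviationConfig",
    "TriggerEvent",
    "compute_baseline",
    "smooth",
    "detect_deviations",
    "gate_and_cap",
]

# Relative guard on the threshold comparison: a noiseless plateau at exactly
# (1+threshold)*baseline must count as "at threshold" despite rounding in the
# moving average. Any meaningful undershoot is orders of magnitude larger.
_REL_GUARD = 1e-12


@dataclass(frozen=True)
class Baseline:
    """Calibrated resting EDA level for one member (µS over a fixed window)."""

    mean_eda_us: float
    window_s: float = 180.0
    n_samples: int = 0
    member_id: str = ""

    def __post_init__(self) -> None:
        if self.mean_eda_us < 0:
            raise ValueError("baseline mean must be >= 0 µS")


@dataclass(frozen=True)
class DeviationConfig:
    """Tunable parameters of the deviation trigger.

    threshold_fraction
        Fractional rise over baseline that counts as a deviation; operative
        default 0.20, configurable down to the 0.15 literature benchmark.
    smooth_window_s
        Width of the centered moving average applied before thresholding.
    sustain_s
        Seconds the smoothed signal must stay at/above threshold to fire,
        so a single SCR spike cannot trigger.
    refractory_s
        Minimum spacing between triggers (default 15 min — one survey
        response window).
    daily_cap
        Maximum deviation notifications emitted per study day.
    """

    threshold_fraction: float = 0.20
    smooth_window_s: float = 5.0
    sustain_s: float = 5.0
    refractory_s: float = 900.0
    daily_cap: int = 4

    def __post_init__(self) -> None:
        if not (0 < self.threshold_fraction < 1):
            raise ValueError("threshold_fraction must lie in (0, 1)")
        if self.daily_cap < 0:
            raise ValueError("daily_cap must be >= 0")
        for name in ("smooth_window_s", "sustain_s", "refractory_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class TriggerEvent:
    """One deviation detection: absolute time, signal level, and provenance."""

    time: float  # absolute POSIX seconds
    smoothed_eda_us: float
    baseline: Baseline
    emitted: bool = False


def compute_baseline(
    stream: EdaStream,
    window_start_s: float = 0.0,
    window_s: float = 180.0,
    member_id: str = "",
) -> Baseline:
    """Mean EDA over the half-open calibration window [start, start+window).

    The 3-minute default at 4 Hz consumes 720 samples. Windows shorter than
    30 s are rejected as too few samples to anchor a relative threshold.
    """
    if window_s < 30.0:
        raise ValueError(f"calibration window must be >= 30 s, got {window_s}")
    fs = stream.sample_rate_hz
    i0 = int(round(window_start_s * fs))
    i1 = i0 + int(round(window_s * fs))
    if window_start_s < 0 or i1 > len(stream):
        raise ValueError(
            f"calibration window [{window_start_s}, {window_start_s + window_s}) s "
            f"extends past the stream ({stream.duration_s} s)"
        )
    window = stream.samples[i0:i1]
    return Baseline(
        mean_eda_us=float(np.mean(window)),
        window_s=window_s,
        n_samples=int(window.size),
        member_id=member_id,
    )


def smooth(stream: EdaStream, smooth_window_s: float) -> EdaStream:
    """Centered moving average with the window truncated at the edges.

    ``smooth_window_s = 0`` is the identity. Each output sample averages the
    raw samples within ± window/2 seconds (inclusive).
    """
    if smooth_window_s < 0:
        raise ValueError("smooth_window_s must be >= 0")
    if smooth_window_s == 0:
        return stream
    half = int(round(smooth_window_s * stream.sample_rate_hz / 2.0))
    if half == 0:
        return stream
    x = stream.samples
    n = len(x)
    csum = np.concatenate(([0.0], np.cumsum(x)))
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half, n - 1)
    out = (csum[hi + 1] - csum[lo]) / (hi - lo + 1)
    return stream.with_samples(out)


def detect_deviations(
    stream: EdaStream, baseline: Baseline, cfg: DeviationConfig = DeviationConfig()
) -> list[TriggerEvent]:
    """Scan a stream forward and return deviation triggers in time order.

    A trigger fires at the first instant the smoothed signal has been at or
    above ``baseline × (1 + threshold_fraction)`` continuously for
    ``sustain_s`` seconds; after a trigger no samples accumulate toward the
    next one until ``refractory_s`` have elapsed. The decision path is a
    single forward pass over the smoothed series, so the same code serves
    offline scoring and stream-time detection.
    """
    if baseline.mean_eda_us <= 0:
        raise ValueError("relative deviation is undefined for a zero baseline")
    fs = stream.sample_rate_hz
    sm = smooth(stream, cfg.smooth_window_s)
    thr = baseline.mean_eda_us * (1.0 + cfg.threshold_fraction)
    above = sm.samples >= thr * (1.0 - _REL_GUARD)
    n_sustain = int(round(cfg.sustain_s * fs)) + 1

    triggers: list[TriggerEvent] = []
    # run-length representation of the boolean series
    padded = np.diff(np.concatenate(([0], above.astype(np.int8), [0])))
    run_starts = np.flatnonzero(padded == 1)
    run_ends = np.flatnonzero(padded == -1)  # exclusive
    last_trigger_t = -np.inf
    for s, e in zip(run_starts, run_ends):
        start = int(s)
        while True:
            if np.isfinite(last_trigger_t):
                earliest = last_trigger_t + cfg.refractory_s - stream.start_time
                min_idx = int(np.ceil(earliest * fs - 1e-9))
                start = max(start, min_idx)
            if e - start < n_sustain:
                break
            ti = start + n_sustain - 1
            t_abs = stream.start_time + ti / fs
            triggers.append(
                TriggerEvent(time=t_abs, smoothed_eda_us=float(sm.samples[ti]), baseline=baseline)
            )
            last_trigger_t = t_abs
            start = ti + 1
    return triggers


def gate_and_cap(
    triggers: Sequence[TriggerEvent],
    design,
    days: Iterable[date] | date | None = None,
) -> list[TriggerEvent]:
    """Apply study-hour gating and the daily notification cap.

    Only triggers inside the study window of their calendar day (in the
    design's timezone) are eligible; of those, the first ``daily_cap`` per
    day are emitted. The cap counter resets at each day's window start.
    ``days`` optionally restricts which calendar days are considered.
    """
    from .scheduler import window_for_day  # avoid circular import

    if isinstance(days, date):
        days = [days]
    allowed = set(days) if days is not None else None
    cap = design.deviation_cfg.daily_cap
    counts: dict[date, int] = {}
    emitted: list[TriggerEvent] = []
    for tr in sorted(triggers, key=lambda t: t.time):
        dt = datetime.fromtimestamp(tr.time, tz=design.tz)
        d = dt.date()
        if allowed is not None and d not in allowed:
            continue
        w0, w1 = window_for_day(design, d)
        if not (w0 <= dt < w1):
            continue
        if counts.get(d, 0) >= cap:
            continue
        counts[d] = counts.get(d, 0) + 1
        emitted.append(replace(tr, emitted=True))
    return emitted
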