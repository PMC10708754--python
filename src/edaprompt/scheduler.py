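"""Stratified random-interval prompt scheduling and notification merging.

Study hours run 16:00–20:00 local on weekdays and 10:00–18:00 on weekends
(keeping prompts clear of school hours). Each day's window is divided into
``n_intervals`` equal half-open intervals and exactly one random survey
prompt is drawn uniformly within each — four random surveys per member per
day for the default ten-day study. A missed prompt earns at most one
reminder, inside the same interval. Deviation-triggered prompts are merged
into the same notification stream; participants cannot tell the kinds apart,
and the blinded export preserves that property.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date, datetime, time, timedelta, timezone
from typing import Sequence

import numpy as np

from .deviation import DeviationConfig, TriggerEvent

__all__ = [
    "StudyDesign",
    "PromptEvent",
    "window_for_day",
    "study_windows",
    "partition_intervals",
    "draw_random_prompts",
    "schedule_reminder",
    "merge_prompt_streams",
    "prompts_to_frame",
    "deviation_prompt",
]


@dataclass(frozen=True)
class StudyDesign:
    """The study configuration: windows, interval counts, caps, thresholds."""

    weekday_window: tuple[time, time] = (time(16, 0), time(20, 0))
    weekend_window: tuple[time, time] = (time(10, 0), time(18, 0))
    n_intervals: int = 4
    n_days: int = 10
    random_reminder: bool = True
    survey_window_min: float = 15.0
    deviation_cfg: DeviationConfig = field(default_factory=DeviationConfig)
    utc_offset_hours: float = 0.0
    reminder_check_lag_s: float = 900.0
    min_gap_s: float = 120.0

    def __post_init__(self) -> None:
        if self.n_intervals < 1:
            raise ValueError("n_intervals must be >= 1")
        if self.n_days < 1:
            raise ValueError("n_days must be >= 1")
        for w in (self.weekday_window, self.weekend_window):
            if w[1] <= w[0]:
                raise ValueError(f"study window must be non-empty, got {w}")

    @property
    def tz(self) -> timezone:
        return timezone(timedelta(hours=self.utc_offset_hours))


@dataclass(frozen=True)
class PromptEvent:
    """A single survey notification and where it sits in the design."""

    member_id: str
    kind: str  # random | deviation | reminder
    scheduled_time: datetime
    day: date
    interval_index: int | None = None
    interval: tuple[datetime, datetime] | None = None
    parent_prompt: "PromptEvent | None" = None

    def __post_init__(self) -> None:
        if self.kind not in {"random", "deviation", "reminder"}:
            raise ValueError(f"unknown prompt kind {self.kind!r}")


def window_for_day(design: StudyDesign, day: date) -> tuple[datetime, datetime]:
    """The study window for one calendar day, as timezone-aware datetimes."""
    w = design.weekday_window if day.weekday() < 5 else design.weekend_window
    return (
        datetime.combine(day, w[0], tzinfo=design.tz),
        datetime.combine(day, w[1], tzinfo=design.tz),
    )


def study_windows(
    design: StudyDesign, start_date: date
) -> list[tuple[date, tuple[datetime, datetime]]]:
    """One (day, window) pair per calendar day for ``design.n_days`` days."""
    out = []
    for k in range(design.n_days):
        d = start_date + timedelta(days=k)
        out.append((d, window_for_day(design, d)))
    return out


def partition_intervals(
    window: tuple[datetime, datetime], n_intervals: int
) -> list[tuple[datetime, datetime]]:
    """Split a window into equal, contiguous, half-open [a, b) intervals."""
    a, b = window
    total = (b - a).total_seconds()
    if total <= 0:
        raise ValueError("window must be non-empty")
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    step, rem = divmod(total, n_intervals)
    if rem != 0 or step != int(step):
        raise ValueError(
            f"window of {total:.0f} s does not divide into {n_intervals} whole-second intervals"
        )
    edges = [a + timedelta(seconds=step * k) for k in range(n_intervals + 1)]
    return list(zip(edges[:-1], edges[1:]))


def draw_random_prompts(
    day_window: tuple[date, tuple[datetime, datetime]],
    n_intervals: int,
    rng_seed: int,
    member_id: str = "",
) -> list[PromptEvent]:
    """Draw exactly one uniformly placed random prompt per interval.

    Deterministic under ``rng_seed``; offsets are continuous uniform over
    each half-open interval.
    """
    day, window = day_window
    intervals = partition_intervals(window, n_intervals)
    rng = np.random.default_rng(rng_seed)
    prompts = []
    for idx, (a, b) in enumerate(intervals):
        offset = rng.uniform(0.0, (b - a).total_seconds())
        prompts.append(
            PromptEvent(
                member_id=member_id,
                kind="random",
                scheduled_time=a + timedelta(seconds=float(offset)),
                day=day,
                interval_index=idx,
                interval=(a, b),
            )
        )
    return prompts


def schedule_reminder(
    prompt: PromptEvent,
    completed: bool,
    now: datetime,
    rng_seed: int,
    check_lag_s: float = 900.0,
) -> PromptEvent | None:
    """At most one reminder for a missed random prompt, inside its interval.

    The reminder time is drawn uniformly between ``max(now, prompt +
    check_lag_s)`` — the earliest point at which the response window has
    lapsed — and the interval end; if no room remains (or the survey was
    completed, or the interval has ended) no reminder is scheduled.
    Deviation prompts never receive reminders.
    """
    if prompt.kind != "random":
        raise ValueError("reminders apply only to random prompts")
    if completed:
        return None
    if prompt.interval is None:
        raise ValueError("prompt carries no interval bounds")
    _, b = prompt.interval
    earliest = max(now, prompt.scheduled_time + timedelta(seconds=check_lag_s))
    if earliest >= b:
        return None
    rng = np.random.default_rng(rng_seed)
    span = (b - earliest).total_seconds()
    t = earliest + timedelta(seconds=float(rng.uniform(0.0, span)))
    return replace(prompt, kind="reminder", scheduled_time=t, parent_prompt=prompt)


def merge_prompt_streams(
    random_prompts: Sequence[PromptEvent],
    deviation_prompts: Sequence[PromptEvent],
    min_gap_s: float = 120.0,
) -> list[PromptEvent]:
    """Time-ordered union of both prompt streams with a minimum gap.

    Whenever two successive notifications would land within ``min_gap_s``,
    the later one is delayed to exactly ``min_gap_s`` after its predecessor
    (a deterministic rule, applied in time order). Kind labels are kept
    internally; use :func:`prompts_to_frame` with ``blinded=True`` for the
    participant-facing view.
    """
    merged = sorted(
        list(random_prompts) + list(deviation_prompts), key=lambda p: p.scheduled_time
    )
    out: list[PromptEvent] = []
    for p in merged:
        if out:
            floor = out[-1].scheduled_time + timedelta(seconds=min_gap_s)
            if p.scheduled_time < floor:
                p = replace(p, scheduled_time=floor)
        out.append(p)
    return out


def prompts_to_frame(prompts: Sequence[PromptEvent], blinded: bool = False):
    """Render prompts as a DataFrame; the blinded view drops every field
    from which the prompt kind could be recovered (kind, interval index)."""
    import pandas as pd

    rows = [
        {
            "member_id": p.member_id,
            "day": p.day.isoformat(),
            "kind": p.kind,
            "scheduled_time_iso": p.scheduled_time.isoformat(),
            "interval_index": p.interval_index if p.interval_index is not None else "",
        }
        for p in prompts
    ]
    df = pd.DataFrame(rows, columns=["member_id", "day", "kind", "scheduled_time_iso", "interval_index"])
    if blinded:
        df = df.drop(columns=["kind", "interval_index"])
    return df


def deviation_prompt(member_id: str, trigger: TriggerEvent, design: StudyDesign) -> PromptEvent:
    """Wrap an emitted deviation trigger as a notification event."""
    dt = datetime.fromtimestamp(trigger.time, tz=design.tz)
    return PromptEvent(member_id=member_id, kind="deviation", scheduled_time=dt, day=dt.date())
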