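from datetime import date, datetime, timedelta, timezone

import numpy as np
import pytest

from edaprompt import (
    DeviationConfig,
    EdaStream,
    MemberProfile,
    PromptEvent,
    StudyDesign,
    SurveyCatalog,
)

MONDAY = date(2023, 5, 1)  # a Monday, so a 10-day run spans both window kinds
UTC = timezone.utc


@pytest.fixture
def design() -> StudyDesign:
    return StudyDesign()


@pytest.fixture
def catalog() -> SurveyCatalog:
    return SurveyCatalog()


@pytest.fixture
def flat_profile() -> MemberProfile:
    """Noise-free profile: constant tonic level, no SCRs/artifacts/episodes."""
    return MemberProfile(
        role="mother",
        tonic_mean_us=1.0,
        tonic_drift_sd=0.0,
        scr_rate_per_min=0.0,
        artifact_rate_per_hour=0.0,
        episode_rate_per_hour=0.0,
    )


def constant_stream(level: float, duration_s: float = 60.0, fs: float = 4.0,
                    start_time: float = 0.0) -> EdaStream:
    return EdaStream(start_time, fs, np.full(int(round(duration_s * fs)), level))


def make_prompt(t: datetime, kind: str = "random", member_id: str = "m",
                interval: tuple[datetime, datetime] | None = None,
                interval_index: int | None = 0) -> PromptEvent:
    return PromptEvent(
        member_id=member_id,
        kind=kind,
        scheduled_time=t,
        day=t.date(),
        interval_index=interval_index if kind == "random" else None,
        interval=interval,
    )
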