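"""Survey instruments and the lifecycle of each issued survey.

Every notification opens a short in-the-moment survey: current emotion (one
of 13), its intensity on a 0–100 slider, current activity (one of 12), and
current company (8 options for children, 9 for parents); parents additionally
rate momentary parenting stress on a 0–100 slider — 4 required questions for
children, 5 for parents. Respondents have 15 minutes from the notification;
at expiry a survey with every required answer is *complete*, one with some
but not all answers is *incomplete*, and one never started is *missed*.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime, timedelta
from typing import Mapping, Sequence

import numpy as np

from .scheduler import PromptEvent
from .synth import MemberProfile

__all__ = [
    "SurveyCatalog",
    "SurveyInstance",
    "TABLE_LABEL_ALIASES",
    "issue_survey",
    "record_answer",
    "finalize_expired",
    "simulate_responses",
    "responses_to_frame",
]

EMOTIONS = (
    "happy", "nervous", "sad", "excited", "relaxed", "frustrated", "scared",
    "angry", "surprised", "proud", "ashamed", "guilty", "disgusted",
)
ACTIVITIES = (
    "homework", "cooking", "chores", "shopping", "eating", "playing games",
    "work", "exercising", "watching TV", "relaxing", "social media",
    "sports/outdoor activities",
)
COMPANY_CHILD = (
    "alone", "mom", "dad", "brother", "sister", "whole family", "friend",
    "group of friends",
)
COMPANY_PARENT = (
    "alone", "significant other", "younger son", "older son",
    "younger daughter", "older daughter", "whole family", "friend",
    "group of friends",
)

#: Alias map used by the report layer: the instrument's emotion labels versus
#: the labels some summary tables print for the same response options.
TABLE_LABEL_ALIASES = {"relaxed": "content", "scared": "afraid/scared"}

_PARENT_ROLES = {"mother", "father"}


@dataclass(frozen=True)
class SurveyCatalog:
    """The fixed response options of the survey instrument.

    Sizes are enforced at construction: exactly 13 emotions, 12 activities,
    8 child-company and 9 parent-company options; both sliders span 0–100.
    """

    emotions: tuple[str, ...] = EMOTIONS
    activities: tuple[str, ...] = ACTIVITIES
    company_child: tuple[str, ...] = COMPANY_CHILD
    company_parent: tuple[str, ...] = COMPANY_PARENT
    intensity_scale: tuple[int, int] = (0, 100)
    parenting_stress_scale: tuple[int, int] = (0, 100)

    def __post_init__(self) -> None:
        for name, seq, n in (
            ("emotions", self.emotions, 13),
            ("activities", self.activities, 12),
            ("company_child", self.company_child, 8),
            ("company_parent", self.company_parent, 9),
        ):
            if len(seq) != n:
                raise ValueError(f"{name} must have exactly {n} entries, got {len(seq)}")

    def company_for(self, role: str) -> tuple[str, ...]:
        return self.company_parent if role in _PARENT_ROLES else self.company_child


def required_fields(role: str) -> tuple[str, ...]:
    base = ("emotion", "intensity", "activity", "company")
    return base + ("parenting_stress",) if role in _PARENT_ROLES else base


@dataclass(frozen=True)
class SurveyInstance:
    """One issued survey: prompt reference, deadline, answers, status."""

    prompt: PromptEvent
    role: str
    issued_at: datetime
    expires_at: datetime
    answers: Mapping[str, object] = field(default_factory=dict)
    status: str = "pending"  # pending | complete | incomplete | missed
    answered_at: datetime | None = None

    @property
    def required(self) -> tuple[str, ...]:
        return required_fields(self.role)

    @property
    def n_required(self) -> int:
        return len(self.required)


def issue_survey(
    prompt: PromptEvent,
    role: str,
    catalog: SurveyCatalog = SurveyCatalog(),
    now: datetime | None = None,
    survey_window_min: float = 15.0,
) -> SurveyInstance:
    """Open a pending survey for a prompt: 4 questions for children, 5 for
    parents, with the response deadline ``survey_window_min`` minutes out."""
    if role not in _PARENT_ROLES | {"child"}:
        raise ValueError(f"unknown role {role!r}")
    issued = now if now is not None else prompt.scheduled_time
    return SurveyInstance(
        prompt=prompt,
        role=role,
        issued_at=issued,
        expires_at=issued + timedelta(minutes=survey_window_min),
    )


def _validate_answer(instance: SurveyInstance, catalog: SurveyCatalog, fld: str, value):
    if fld not in instance.required:
        raise ValueError(f"field {fld!r} is not part of a {instance.role} survey")
    if fld == "emotion":
        if value not in catalog.emotions:
            raise ValueError(f"emotion {value!r} is not one of the 13 catalog labels")
    elif fld == "activity":
        if value not in catalog.activities:
            raise ValueError(f"activity {value!r} is not one of the 12 catalog labels")
    elif fld == "company":
        options = catalog.company_for(instance.role)
        if value not in options:
            raise ValueError(f"company {value!r} is not a valid option for role {instance.role}")
    elif fld in ("intensity", "parenting_stress"):
        lo, hi = (catalog.intensity_scale if fld == "intensity"
                  else catalog.parenting_stress_scale)
        if not isinstance(value, (int, np.integer)) or isinstance(value, bool):
            raise ValueError(f"{fld} must be an integer, got {value!r}")
        if not (lo <= value <= hi):
            raise ValueError(f"{fld} must lie in [{lo}, {hi}], got {value}")


def record_answer(
    instance: SurveyInstance,
    fld: str,
    value,
    now: datetime,
    catalog: SurveyCatalog = SurveyCatalog(),
) -> SurveyInstance:
    """Record one validated answer; the expiry boundary is exclusive.

    An answer arriving at or after ``expires_at`` is rejected. When the last
    required answer lands, the instance transitions to *complete*.
    """
    if instance.status != "pending":
        raise ValueError(f"survey is {instance.status}; answers are closed")
    if now >= instance.expires_at:
        raise ValueError(
            f"answer at {now.isoformat()} rejected: survey expired at "
            f"{instance.expires_at.isoformat()}"
        )
    _validate_answer(instance, catalog, fld, value)
    answers = dict(instance.answers)
    answers[fld] = value
    status = "complete" if all(f in answers for f in instance.required) else "pending"
    return replace(instance, answers=answers, status=status, answered_at=now)


def _classify(instance: SurveyInstance) -> str:
    if all(f in instance.answers for f in instance.required):
        return "complete"
    return "incomplete" if instance.answers else "missed"


def finalize_expired(
    instances: Sequence[SurveyInstance], now: datetime
) -> list[SurveyInstance]:
    """Classify every pending survey past its deadline; idempotent."""
    out = []
    for inst in instances:
        if inst.status == "pending" and now >= inst.expires_at:
            inst = replace(inst, status=_classify(inst))
        out.append(inst)
    return out


def simulate_responses(
    instances: Sequence[SurveyInstance],
    profile: MemberProfile,
    catalog: SurveyCatalog = SurveyCatalog(),
    seed: int = 0,
    partial_prob: float = 0.05,
    emotion_weights: Sequence[float] | None = None,
    activity_weights: Sequence[float] | None = None,
) -> list[SurveyInstance]:
    """Answer surveys according to the member's response-behaviour model.

    Each instance is answered fully with the profile's kind-specific
    response probability, partially (a random proper subset of required
    answers) with ``partial_prob``, and otherwise ignored. Answer times are
    uniform within the response window; content is drawn from categorical
    distributions over the catalog (uniform by default). Deterministic
    under ``seed``.
    """
    if not (0 <= partial_prob <= 1):
        raise ValueError("partial_prob must lie in [0, 1]")
    for name in ("response_prob_random", "response_prob_deviation"):
        p = getattr(profile, name)
        if p + partial_prob > 1 + 1e-12:
            raise ValueError(f"{name} + partial_prob exceeds 1")
    rng = np.random.default_rng(seed)
    e_w = _norm_weights(emotion_weights, len(catalog.emotions))
    a_w = _norm_weights(activity_weights, len(catalog.activities))
    out = []
    for inst in instances:
        kind = inst.prompt.kind
        p_full = (
            profile.response_prob_deviation
            if kind == "deviation"
            else profile.response_prob_random
        )
        u = rng.uniform()
        if u < p_full:
            n_answer = inst.n_required
        elif u < p_full + partial_prob:
            n_answer = int(rng.integers(1, inst.n_required))
        else:
            n_answer = 0
        if n_answer:
            window_s = (inst.expires_at - inst.issued_at).total_seconds()
            at = inst.issued_at + timedelta(seconds=float(rng.uniform(0.0, window_s * 0.999)))
            fields_order = list(inst.required)
            if n_answer < inst.n_required:
                picks = rng.choice(len(fields_order), size=n_answer, replace=False)
                fields_order = [fields_order[i] for i in sorted(picks)]
            for fld in fields_order:
                value = _draw_value(rng, fld, inst, catalog, e_w, a_w)
                inst = record_answer(inst, fld, value, now=at, catalog=catalog)
        out.append(inst)
    return out


def _norm_weights(w: Sequence[float] | None, n: int) -> np.ndarray:
    if w is None:
        return np.full(n, 1.0 / n)
    w = np.asarray(w, dtype=float)
    if w.size != n or np.any(w < 0) or w.sum() == 0:
        raise ValueError(f"weights must be {n} nonnegative values with positive sum")
    return w / w.sum()


def _draw_value(rng, fld, inst, catalog, e_w, a_w):
    if fld == "emotion":
        return catalog.emotions[int(rng.choice(len(catalog.emotions), p=e_w))]
    if fld == "activity":
        return catalog.activities[int(rng.choice(len(catalog.activities), p=a_w))]
    if fld == "company":
        options = catalog.company_for(inst.role)
        return options[int(rng.integers(len(options)))]
    return int(rng.integers(0, 101))


def responses_to_frame(instances: Sequence[SurveyInstance], blinded: bool = False):
    """Response log as a DataFrame (one row per issued survey)."""
    import pandas as pd

    rows = []
    for inst in instances:
        rows.append(
            {
                "member_id": inst.prompt.member_id,
                "role": inst.role,
                "kind": inst.prompt.kind,
                "issued_iso": inst.issued_at.isoformat(),
                "answered_iso": inst.answered_at.isoformat() if inst.answered_at else "",
                "emotion": inst.answers.get("emotion", ""),
                "intensity": inst.answers.get("intensity", ""),
                "activity": inst.answers.get("activity", ""),
                "company": inst.answers.get("company", ""),
                "parenting_stress": inst.answers.get("parenting_stress", ""),
                "status": inst.status,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=[
            "member_id", "role", "kind", "issued_iso", "answered_iso", "emotion",
            "intensity", "activity", "company", "parenting_stress", "status",
        ],
    )
    if blinded:
        df = df.drop(columns=["kind"])
    return df
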