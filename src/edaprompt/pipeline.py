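"""End-to-end study simulation: signals → detection → prompts → surveys → reports.

One :class:`RunConfig` (a study design, a family roster, and a master seed)
reproduces an entire simulated deployment: per-member EDA streams in the
E4-style CSV dialect, baseline calibrations, deviation trigger logs, the
merged prompt schedule, simulated survey responses, and the analytics
reports. Re-running the same config and seed reproduces byte-identical
outputs; the manifest records the config hash and every derived seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date, datetime, timedelta
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analytics, deviation, scheduler, streams, survey, synth

__all__ = ["RunConfig", "simulate_study", "load_config"]

log = logging.getLogger("edaprompt")

DEFAULT_ROSTER = (
    ("mother", "mother"),
    ("father", "father"),
    ("child1", "child"),
    ("child2", "child"),
)


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one simulated study run."""

    design: scheduler.StudyDesign = field(default_factory=scheduler.StudyDesign)
    roster: tuple[tuple[str, str, synth.MemberProfile], ...] = ()
    master_seed: int = 0
    start_date: date = date(2023, 5, 1)  # a Monday
    out_dir: str = "run"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        roster = self.roster
        if not roster:
            profiles = synth.default_profiles()
            roster = tuple(
                (mid, role, profiles[role]) for mid, role in DEFAULT_ROSTER
            )
            object.__setattr__(self, "roster", roster)
        if len(self.roster) < 1:
            raise ValueError("roster must contain at least one member")

    def to_dict(self) -> dict:
        d = self.design
        return {
            "design": {
                "weekday_window": [t.isoformat() for t in d.weekday_window],
                "weekend_window": [t.isoformat() for t in d.weekend_window],
                "n_intervals": d.n_intervals,
                "n_days": d.n_days,
                "random_reminder": d.random_reminder,
                "survey_window_min": d.survey_window_min,
                "utc_offset_hours": d.utc_offset_hours,
                "min_gap_s": d.min_gap_s,
                "deviation": {
                    "threshold_fraction": d.deviation_cfg.threshold_fraction,
                    "smooth_window_s": d.deviation_cfg.smooth_window_s,
                    "sustain_s": d.deviation_cfg.sustain_s,
                    "refractory_s": d.deviation_cfg.refractory_s,
                    "daily_cap": d.deviation_cfg.daily_cap,
                },
            },
            "roster": [
                {"member_id": mid, "role": role, "tonic_mean_us": p.tonic_mean_us,
                 "response_prob_random": p.response_prob_random,
                 "response_prob_deviation": p.response_prob_deviation}
                for mid, role, p in self.roster
            ],
            "master_seed": self.master_seed,
            "start_date": self.start_date.isoformat(),
        }


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file plus keyword overrides.

    Recognised top-level keys: ``design`` (StudyDesign fields, with
    ``deviation`` nested), ``roster`` (list of member mappings), ``master_seed``,
    ``start_date``. CLI flags override file values.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    dsn_raw = dict(raw.get("design", {}))
    dev_raw = dict(dsn_raw.pop("deviation", {}))
    dev_cfg = deviation.DeviationConfig(**dev_raw)
    for key in ("weekday_window", "weekend_window"):
        if key in dsn_raw:
            from datetime import time
            dsn_raw[key] = tuple(time.fromisoformat(t) for t in dsn_raw[key])
    design = scheduler.StudyDesign(deviation_cfg=dev_cfg, **dsn_raw)
    roster = []
    for m in raw.get("roster", []):
        m = dict(m)
        mid = m.pop("member_id")
        role = m.pop("role")
        roster.append((mid, role, synth.MemberProfile(role=role, **m)))
    kwargs = {
        "design": design,
        "roster": tuple(roster),
        "master_seed": int(raw.get("master_seed", 0)),
    }
    if "start_date" in raw:
        kwargs["start_date"] = date.fromisoformat(str(raw["start_date"]))
    kwargs.update(overrides)
    return RunConfig(**kwargs)


def derive_seed(master_seed: int, *key: int) -> int:
    """Deterministic child seed (< 2^31) for a (member, day, stage) key."""
    ss = np.random.SeedSequence(master_seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def simulate_study(config: RunConfig) -> Path:
    """Run the full simulated study and write a reproducible run directory.

    Writes per-member/day EDA streams (E4 CSV), baseline JSONs, the trigger
    log, the merged schedule (plus a blinded view), the response log, the
    analytics reports, and a manifest with the config hash and per-file
    checksums. Refuses to write into a non-empty directory that does not
    look like a previous run.
    """
    out = Path(config.out_dir)
    if out.exists() and any(out.iterdir()) and not (out / "manifest.json").exists():
        raise FileExistsError(
            f"{out} is non-empty and has no manifest.json; refusing to overwrite "
            "a directory that is not a previous run"
        )
    (out / "streams").mkdir(parents=True, exist_ok=True)
    (out / "reports").mkdir(parents=True, exist_ok=True)

    design = config.design
    windows = scheduler.study_windows(design, config.start_date)
    all_prompts: list[scheduler.PromptEvent] = []
    trigger_rows: list[dict] = []
    instances: list[survey.SurveyInstance] = []
    catalog = survey.SurveyCatalog()
    baselines: dict[str, deviation.Baseline] = {}

    for mi, (member_id, role, profile) in enumerate(config.roster):
        cal_seed = derive_seed(config.master_seed, mi, 0, 0)
        cal_start = windows[0][1][0] - timedelta(days=1)
        cal = synth.simulate_tonic(profile, 180.0, cal_seed, start_time=cal_start.timestamp())
        baseline = deviation.compute_baseline(cal, 0.0, 180.0, member_id=member_id)
        baselines[member_id] = baseline
        streams.write_e4_csv(cal, out / "streams" / f"{member_id}_calibration.csv")

        for di, (day, window) in enumerate(windows):
            sess_seed = derive_seed(config.master_seed, mi, di, 1)
            stream, truth = synth.simulate_member_session(profile, design, day, sess_seed)
            streams.write_e4_csv(stream, out / "streams" / f"{member_id}_{day.isoformat()}.csv")

            triggers = deviation.detect_deviations(stream, baseline, design.deviation_cfg)
            emitted = deviation.gate_and_cap(triggers, design, day)
            emitted_times = {t.time for t in emitted}
            for tr in triggers:
                trigger_rows.append({
                    "member_id": member_id,
                    "day": day.isoformat(),
                    "trigger_time_iso": datetime.fromtimestamp(tr.time, tz=design.tz).isoformat(),
                    "smoothed_eda_us": f"{tr.smoothed_eda_us:.6f}",
                    "baseline_us": f"{baseline.mean_eda_us:.6f}",
                    "emitted": int(tr.time in emitted_times),
                })

            rand_seed = derive_seed(config.master_seed, mi, di, 2)
            randoms = scheduler.draw_random_prompts(
                (day, window), design.n_intervals, rand_seed, member_id=member_id
            )
            dev_prompts = [scheduler.deviation_prompt(member_id, t, design) for t in emitted]
            merged = scheduler.merge_prompt_streams(randoms, dev_prompts, design.min_gap_s)

            day_instances = [
                survey.issue_survey(p, role, catalog, survey_window_min=design.survey_window_min)
                for p in merged
            ]
            resp_seed = derive_seed(config.master_seed, mi, di, 3)
            day_instances = survey.simulate_responses(day_instances, profile, catalog, resp_seed)
            day_end = window[1] + timedelta(minutes=design.survey_window_min)
            day_instances = survey.finalize_expired(day_instances, day_end)

            reminders = []
            if design.random_reminder:
                for k, inst in enumerate(day_instances):
                    p = inst.prompt
                    if p.kind != "random":
                        continue
                    rem = scheduler.schedule_reminder(
                        p, inst.status == "complete",
                        now=p.scheduled_time + timedelta(seconds=design.reminder_check_lag_s),
                        rng_seed=derive_seed(config.master_seed, mi, di, 4 + k),
                        check_lag_s=design.reminder_check_lag_s,
                    )
                    if rem is not None:
                        reminders.append(rem)

            all_prompts.extend(merged + reminders)
            instances.extend(day_instances)
            log.info(
                "%s %s: %d prompts (%d deviation, %d reminders), %d complete",
                member_id, day.isoformat(), len(merged), len(dev_prompts), len(reminders),
                sum(1 for i in day_instances if i.status == "complete"),
            )

    all_prompts.sort(key=lambda p: (p.member_id, p.scheduled_time))
    scheduler.prompts_to_frame(all_prompts).to_csv(out / "schedule.csv", index=False)
    scheduler.prompts_to_frame(all_prompts, blinded=True).to_csv(
        out / "schedule_blinded.csv", index=False
    )
    pd.DataFrame(trigger_rows).to_csv(out / "triggers.csv", index=False)
    resp = survey.responses_to_frame(instances)
    resp.to_csv(out / "responses.csv", index=False)
    with open(out / "baselines.json", "w") as fh:
        json.dump(
            {m: {"member_id": b.member_id, "mean_eda_us": round(b.mean_eda_us, 9),
                 "window_s": b.window_s, "n_samples": b.n_samples}
             for m, b in sorted(baselines.items())},
            fh, indent=2, sort_keys=True,
        )

    write_reports(resp, out / "reports")

    cfg_dict = config.to_dict()
    cfg_json = json.dumps(cfg_dict, sort_keys=True)
    files = sorted(
        str(p.relative_to(out))
        for p in out.rglob("*")
        if p.is_file() and p.name != "manifest.json"
    )
    manifest = {
        "config": cfg_dict,
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "master_seed": config.master_seed,
        "files": {f: _sha256(out / f) for f in files},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out


def write_reports(resp: pd.DataFrame, report_dir: Path) -> None:
    """Engagement, endorsement and summary reports from a response log."""
    report_dir = Path(report_dir)
    report_dir.mkdir(parents=True, exist_ok=True)
    summaries = analytics.engagement(resp)
    eng = pd.DataFrame(
        [
            {"member_id": s.member_id, "role": s.role, "kind": s.kind,
             "n_received": s.n_received, "n_complete": s.n_complete,
             "rate_pct": "" if not s.defined else f"{s.rate_pct:.2f}",
             "defined": int(s.defined)}
            for s in summaries
        ]
    )
    eng.to_csv(report_dir / "engagement.csv", index=False)
    answered = resp[resp["status"].isin(["complete", "incomplete"])]
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small runs can have empty role/kind cells
        emo = analytics.endorsement_table(
            answered, survey.EMOTIONS, "emotion", aliases=survey.TABLE_LABEL_ALIASES
        )
        act = analytics.endorsement_table(answered, survey.ACTIVITIES, "activity")
    analytics.render_endorsement(emo).to_csv(report_dir / "endorsement_emotions.csv")
    analytics.render_endorsement(act).to_csv(report_dir / "endorsement_activities.csv")
    summary = {
        "engagement_pooled_pct": round(analytics.study_engagement(resp, "pooled"), 4),
        "engagement_member_mean_pct": round(analytics.study_engagement(resp, "member_mean"), 4),
        "engagement_random_pooled_pct": round(
            analytics.study_engagement(resp, "pooled", kind="random"), 4),
        "engagement_deviation_pooled_pct": round(
            analytics.study_engagement(resp, "pooled", kind="deviation"), 4),
        "n_surveys": int(len(resp)),
    }
    with open(report_dir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
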