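"""Synthetic electrodermal-activity generator with known ground truth.

Builds per-member EDA streams out of four layers so downstream deviation
detection can be scored against injected truth without any device:

1. a slowly drifting *tonic* level (mean-reverting AR(1), resting range
   0–2 µS),
2. spontaneous *phasic* skin-conductance responses (SCRs) with biexponential
   morphology,
3. *arousal episodes* that multiply the tonic level by a known factor — the
   ground truth a percent-over-baseline detector is meant to recover,
4. brief motion *artifacts* (symmetric spikes, clipped at 0 µS).

All randomness flows from explicit integer seeds; there is no global RNG
state anywhere in the module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

from .streams import DEFAULT_SAMPLE_RATE_HZ, EdaStream

__all__ = [
    "ScrEvent",
    "ArousalEpisode",
    "MemberProfile",
    "SessionTruth",
    "default_profiles",
    "simulate_tonic",
    "superimpose_scrs",
    "apply_episodes",
    "add_artifacts",
    "simulate_member_session",
]


@dataclass(frozen=True)
class ScrEvent:
    """One phasic skin-conductance response.

    The waveform is ``amplitude * (exp(-t/decay_tau) - exp(-t/rise_tau)) / norm``
    for t >= 0 after onset, with ``norm`` chosen so the peak equals
    ``amplitude_us``. Defaults follow typical SCR morphology (~0.75 s rise,
    ~2 s recovery).
    """

    onset_s: float
    amplitude_us: float
    rise_tau_s: float = 0.75
    decay_tau_s: float = 2.0

    def __post_init__(self) -> None:
        if self.amplitude_us <= 0:
            raise ValueError("SCR amplitude must be > 0 µS")
        if not (self.decay_tau_s > self.rise_tau_s > 0):
            raise ValueError("need decay_tau_s > rise_tau_s > 0")

    def kernel(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the unit-free biexponential at times ``t`` since onset."""
        t = np.asarray(t, dtype=float)
        r, d = self.rise_tau_s, self.decay_tau_s
        t_peak = (r * d / (d - r)) * math.log(d / r)
        norm = math.exp(-t_peak / d) - math.exp(-t_peak / r)
        out = np.zeros_like(t)
        pos = t >= 0
        out[pos] = self.amplitude_us * (np.exp(-t[pos] / d) - np.exp(-t[pos] / r)) / norm
        return out


@dataclass(frozen=True)
class ArousalEpisode:
    """Ground-truth arousal interval multiplying the tonic level.

    ``level_multiplier`` is dimensionless and >= 1; a 1.25 episode is a
    sustained 25% rise over whatever the tonic level was, which a detector
    thresholding at 20% over baseline should recover.
    """

    start_s: float
    end_s: float
    level_multiplier: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError("episode must have end_s > start_s")
        if self.level_multiplier < 1:
            raise ValueError("level_multiplier must be >= 1")


@dataclass(frozen=True)
class MemberProfile:
    """Generative parameters for one family member's signal and behaviour.

    ``tonic_mean_us`` is the resting skin-conductance level (<= 2 µS for a
    resting adult or child); ``tonic_drift_sd`` the stationary SD of the slow
    drift around it. Response probabilities give the chance of fully
    completing a survey of each prompt kind, and are the member's behavioural
    ground truth for the analytics layer.
    """

    role: str
    tonic_mean_us: float = 1.2
    tonic_drift_sd: float = 0.01
    scr_rate_per_min: float = 1.5
    artifact_rate_per_hour: float = 2.0
    response_prob_random: float = 0.8
    response_prob_deviation: float = 0.75
    episode_rate_per_hour: float = 0.6
    episode_level_range: tuple[float, float] = (1.10, 1.35)
    episode_duration_s: tuple[float, float] = (60.0, 300.0)

    def __post_init__(self) -> None:
        if self.role not in {"mother", "father", "child"}:
            raise ValueError(f"unknown role {self.role!r}")
        if not (0 < self.tonic_mean_us <= 2):
            raise ValueError("tonic_mean_us must lie in (0, 2] µS (resting range)")
        for name in ("tonic_drift_sd", "scr_rate_per_min", "artifact_rate_per_hour",
                     "episode_rate_per_hour"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("response_prob_random", "response_prob_deviation"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")


def default_profiles() -> dict[str, MemberProfile]:
    """Default roster profiles for a two-parent, two-child family.

    Response probabilities follow the role-specific mean response rates
    reported for this study design (mothers most responsive to random
    prompts, children least; children most responsive to deviation prompts).
    """
    return {
        "mother": MemberProfile(role="mother", tonic_mean_us=1.1,
                                response_prob_random=0.80, response_prob_deviation=0.74),
        "father": MemberProfile(role="father", tonic_mean_us=1.3,
                                response_prob_random=0.68, response_prob_deviation=0.65),
        "child": MemberProfile(role="child", tonic_mean_us=0.9,
                               response_prob_random=0.45, response_prob_deviation=0.77),
    }


@dataclass(frozen=True)
class SessionTruth:
    """Ground truth injected into one simulated session."""

    episodes: tuple[ArousalEpisode, ...] = ()
    scrs: tuple[ScrEvent, ...] = ()
    artifact_times_s: tuple[float, ...] = ()


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(child.generate_state(1)[0] % (2**31)) for child in ss.spawn(n)]


def simulate_tonic(
    profile: MemberProfile,
    duration_s: float,
    seed: int,
    sample_rate_hz: float = DEFAULT_SAMPLE_RATE_HZ,
    start_time: float = 0.0,
    reversion_time_s: float = 300.0,
) -> EdaStream:
    """Simulate the slowly drifting tonic skin-conductance level.

    The drift is a stationary mean-reverting AR(1) (discretised
    Ornstein–Uhlenbeck) with stationary SD ``profile.tonic_drift_sd`` and a
    ~5-minute reversion time, added to ``profile.tonic_mean_us`` and clipped
    at 0 µS. ``tonic_drift_sd = 0`` yields a constant trace.
    """
    if duration_s <= 0:
        raise ValueError(f"duration_s must be > 0, got {duration_s}")
    n = int(round(duration_s * sample_rate_hz))
    if n < 1:
        raise ValueError("duration too short for one sample at this rate")
    if profile.tonic_drift_sd == 0:
        samples = np.full(n, profile.tonic_mean_us)
        return EdaStream(start_time, sample_rate_hz, samples)
    rng = np.random.default_rng(seed)
    dt = 1.0 / sample_rate_hz
    phi = math.exp(-dt / reversion_time_s)
    eps_sd = profile.tonic_drift_sd * math.sqrt(1.0 - phi * phi)
    x0 = rng.normal(0.0, profile.tonic_drift_sd)
    eps = rng.normal(0.0, eps_sd, size=n)
    drift, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))
    samples = np.clip(profile.tonic_mean_us + drift, 0.0, None)
    return EdaStream(start_time, sample_rate_hz, samples)


def superimpose_scrs(stream: EdaStream, events: Sequence[ScrEvent]) -> EdaStream:
    """Add phasic SCR waveforms onto ``stream``.

    Each event contributes its biexponential kernel from its onset onward;
    the kernel is rescaled so its maximum over the *sampled* grid equals the
    event amplitude (the continuous peak can fall between samples).
    Contributions sum, so the output is everywhere >= the input.
    """
    for ev in events:
        if not (0 <= ev.onset_s < stream.duration_s):
            raise ValueError(
                f"SCR onset {ev.onset_s} s lies outside stream duration {stream.duration_s} s"
            )
    out = stream.samples.copy()
    t = stream.times_s
    fs = stream.sample_rate_hz
    for ev in events:
        i0 = int(math.floor(ev.onset_s * fs))
        # kernel support truncated where it has decayed to ~1e-5 of peak
        i1 = min(len(out), i0 + int(math.ceil(12 * ev.decay_tau_s * fs)) + 1)
        k = ev.kernel(t[i0:i1] - ev.onset_s)
        peak = k.max()
        if peak > 0:
            k *= ev.amplitude_us / peak
        out[i0:i1] += k
    return stream.with_samples(out)


def _episode_multiplier(ep: ArousalEpisode, t: np.ndarray, ramp_s: float) -> np.ndarray:
    if ramp_s <= 0:
        inside = (t >= ep.start_s) & (t <= ep.end_s)
        return np.where(inside, ep.level_multiplier, 1.0)
    up = (t - ep.start_s) / ramp_s
    down = (ep.end_s + ramp_s - t) / ramp_s
    frac = np.clip(np.minimum.reduce([up, down, np.ones_like(t)]), 0.0, 1.0)
    return 1.0 + (ep.level_multiplier - 1.0) * frac


def apply_episodes(
    stream: EdaStream, episodes: Sequence[ArousalEpisode], ramp_s: float = 10.0
) -> EdaStream:
    """Scale the stream by each episode's level multiplier.

    The multiplier ramps up linearly over ``ramp_s`` seconds, holds at
    ``level_multiplier`` until ``end_s``, then ramps back down; outside all
    episodes the stream is untouched. Episodes multiply (rather than add)
    so a "20% increase" is well defined relative to any baseline level.
    Overlapping ramps combine by taking the pointwise maximum multiplier.
    """
    eps = sorted(episodes, key=lambda e: e.start_s)
    for a, b in zip(eps, eps[1:]):
        if b.start_s < a.end_s:
            raise ValueError(
                f"episodes overlap: [{a.start_s}, {a.end_s}] and [{b.start_s}, {b.end_s}]"
            )
    if not eps:
        return stream
    t = stream.times_s
    mult = np.ones_like(t)
    for ep in eps:
        np.maximum(mult, _episode_multiplier(ep, t, ramp_s), out=mult)
    return stream.with_samples(stream.samples * mult)


def add_artifacts(
    stream: EdaStream, rate_per_hour: float, seed: int
) -> tuple[EdaStream, np.ndarray]:
    """Insert brief motion-artifact spikes and return their ground-truth times.

    Artifact onsets are Poisson with the given hourly rate; each spike is a
    triangular transient of <= 2 s, positive or negative with equal
    probability, and the result is clipped at 0 µS. Rate 0 is the identity.
    """
    if rate_per_hour < 0:
        raise ValueError("artifact rate must be >= 0 per hour")
    if rate_per_hour == 0:
        return stream, np.empty(0)
    rng = np.random.default_rng(seed)
    dur = stream.duration_s
    n = rng.poisson(rate_per_hour * dur / 3600.0)
    if n == 0:
        return stream, np.empty(0)
    times = np.sort(rng.uniform(0.0, dur, size=n))
    widths = rng.uniform(0.25, 2.0, size=n)
    amps = rng.uniform(0.2, 1.0, size=n) * rng.choice([-1.0, 1.0], size=n)
    out = stream.samples.copy()
    t = stream.times_s
    for t0, w, a in zip(times, widths, amps):
        half = w / 2.0
        local = slice(
            max(0, int((t0 - half) * stream.sample_rate_hz)),
            min(len(out), int(math.ceil((t0 + half) * stream.sample_rate_hz)) + 1),
        )
        shape = np.clip(1.0 - np.abs(t[local] - t0) / half, 0.0, 1.0)
        out[local] += a * shape
    return stream.with_samples(np.clip(out, 0.0, None)), times


def _draw_episodes(
    rng: np.random.Generator, profile: MemberProfile, duration_s: float
) -> tuple[ArousalEpisode, ...]:
    n = rng.poisson(profile.episode_rate_per_hour * duration_s / 3600.0)
    if n == 0:
        return ()
    starts = np.sort(rng.uniform(0.0, duration_s, size=n))
    lo_d, hi_d = profile.episode_duration_s
    durs = rng.uniform(lo_d, hi_d, size=n)
    lo_l, hi_l = profile.episode_level_range
    levels = rng.uniform(lo_l, hi_l, size=n)
    eps: list[ArousalEpisode] = []
    for s, d, lvl in zip(starts, durs, levels):
        end = min(s + d, duration_s)
        if end - s < 1.0:
            continue
        if eps and s < eps[-1].end_s + 30.0:  # keep episodes separated
            continue
        eps.append(ArousalEpisode(start_s=float(s), end_s=float(end), level_multiplier=float(lvl)))
    return tuple(eps)


def _draw_scrs(
    rng: np.random.Generator, profile: MemberProfile, duration_s: float
) -> tuple[ScrEvent, ...]:
    n = rng.poisson(profile.scr_rate_per_min * duration_s / 60.0)
    if n == 0:
        return ()
    onsets = np.sort(rng.uniform(0.0, duration_s, size=n))
    amps = rng.lognormal(mean=math.log(0.05), sigma=0.5, size=n)
    return tuple(
        ScrEvent(onset_s=float(o), amplitude_us=float(a)) for o, a in zip(onsets, amps)
    )


def simulate_member_session(
    profile: MemberProfile,
    design,
    day: date,
    seed: int,
    episodes: Sequence[ArousalEpisode] | None = None,
    with_scrs: bool = True,
    artifact_rate_per_hour: float | None = None,
) -> tuple[EdaStream, SessionTruth]:
    """Compose one member's EDA stream over the day's study window.

    Layers tonic drift, ground-truth arousal episodes (drawn from the
    profile's episode rate unless given explicitly), spontaneous SCRs and
    motion artifacts. Deterministic under (profile, design, day, seed); the
    returned :class:`SessionTruth` is sufficient to score detector
    sensitivity and false alarms.

    ``design`` is a :class:`~edaprompt.scheduler.StudyDesign` (duck-typed:
    only its window lookup is used).
    """
    from .scheduler import window_for_day  # local import to avoid a cycle

    w0, w1 = window_for_day(design, day)
    duration_s = (w1 - w0).total_seconds()
    s_tonic, s_epi, s_scr, s_art = _child_seeds(seed, 4)
    stream = simulate_tonic(profile, duration_s, s_tonic, start_time=w0.timestamp())
    rng_epi = np.random.default_rng(s_epi)
    eps = tuple(episodes) if episodes is not None else _draw_episodes(rng_epi, profile, duration_s)
    stream = apply_episodes(stream, eps)
    scrs: tuple[ScrEvent, ...] = ()
    if with_scrs and profile.scr_rate_per_min > 0:
        scrs = _draw_scrs(np.random.default_rng(s_scr), profile, duration_s)
        stream = superimpose_scrs(stream, scrs)
    art_rate = profile.artifact_rate_per_hour if artifact_rate_per_hour is None else artifact_rate_per_hour
    stream, art_times = add_artifacts(stream, art_rate, s_art)
    return stream, SessionTruth(episodes=eps, scrs=scrs, artifact_times_s=tuple(art_times))
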