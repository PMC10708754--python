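# Methods

This note documents the models behind `edaprompt`: what the synthetic signal
generator emulates, how the deviation trigger is defined, the scheduling and
survey rules, the statistics in the analytics layer, and the numerical and
design choices made where the underlying protocol leaves them open.

## The signal model

Electrodermal activity (EDA) is skin conductance in microsiemens (µS),
sampled at 4 Hz as by the EDA channel of common wrist wearables. The
generator composes four layers, each with explicit ground truth:

**Tonic level.** A mean-reverting AR(1) (a discretised Ornstein–Uhlenbeck
process) around the member's resting level `tonic_mean_us`, with stationary
SD `tonic_drift_sd` and a 5-minute reversion time, clipped at 0 µS. Resting
levels default to ~0.9–1.3 µS across roles, inside the 0–2 µS range typical
of unstimulated skin. The default drift SD is 0.01 µS: large enough that the
calibration baseline and session tonic visibly differ, small enough that a
sustained 25% arousal episode always clears a 20% detection threshold — a
stated requirement on the generator (see *Ground-truth sufficiency* below).

**Phasic SCRs.** Spontaneous skin-conductance responses with the classic
biexponential shape `A·(e^{−t/τ_d} − e^{−t/τ_r})/norm`, τ_r = 0.75 s,
τ_d = 2.0 s, at 1.5 events/min. Amplitudes are log-normal with median
0.05 µS (σ_log = 0.5), matching the small nonspecific SCRs seen at the
wrist. Each event's sampled kernel is rescaled so its maximum equals the
event amplitude exactly (the continuous peak at ≈1.18 s falls between 4-Hz
samples); kernel tails are truncated at 12 decay constants (~10⁻⁵ of peak).

**Arousal episodes** are the detector's ground truth: intervals during which
the tonic level is *multiplied* by a known factor (default draws:
1.10–1.35×, 60–300 s, 0.6/h). Multiplying rather than adding keeps "a 20%
increase" well defined relative to any baseline. The multiplier ramps
linearly over 10 s at both edges; overlapping ramps combine by pointwise
maximum. Episodes themselves may not overlap.

**Artifacts** model motion noise: Poisson-timed triangular spikes of ≤2 s,
0.2–1.0 µS, positive or negative with equal probability, clipped at 0 µS.

All four layers draw from independent child seeds of one session seed
(`numpy.random.SeedSequence` spawning); there is no global RNG state, and
identical inputs reproduce identical streams bit for bit.

What the generator does **not** emulate: circadian tonic trends, electrode
drying/contact drift, temperature coupling, device dropouts, or the
heavy-tailed artifact bursts of real ambulatory recordings. Passing tests
therefore establish the *algorithms'* correctness under controlled
conditions, not field performance of any device.

## Baseline and deviation trigger

The baseline is the arithmetic mean over a half-open 3-minute calibration
window — 720 samples at 4 Hz — mirroring a researcher-led orientation
recording; windows under 30 s are rejected as statistically meaningless.
There is no within-day re-baselining: deviations are always relative to the
one calibration value.

Detection compares a **centered moving average** (default 5 s, edge-truncated)
against `baseline × (1 + θ)`. The operative threshold is θ = 0.20 — the
strict end of the 15–20% range used for meaningful sympathetic arousal — and
θ = 0.15 is reachable by configuration. A trigger fires at the first instant
the smoothed signal has been at/above threshold continuously for `sustain_s`
(default 5 s, so one SCR spike cannot fire it); after a trigger, no samples
accumulate toward the next until `refractory_s` (default 15 min, one survey
window) has elapsed. Sustain and refractory are implementation parameters:
the protocol being modelled does not state them, and the defaults are chosen
so triggers cannot pile up inside a single survey's response window.

Numerical choices: the threshold comparison uses a relative guard of 10⁻¹²,
so a noiseless plateau at *exactly* `1.20 × baseline` counts as at-threshold
despite rounding in the moving average, while any physical undershoot (the
tests use 10⁻⁶ µS) does not trigger. The detector is a single forward pass
over the smoothed series and is verified equivalent to an exhaustive
per-sample offline scan; because the smoother is centered, a literal
real-time port would buffer half a smoothing window (2.5 s) before deciding.

Emitted notifications are gated to the day's study hours and capped at
**4 per day**, with the counter resetting at each day's window start. The cap
counts notifications sent, not surveys completed.

## Scheduling and surveys

Study hours are 16:00–20:00 local on weekdays and 10:00–18:00 on weekends,
partitioned into 4 equal **half-open** intervals `[a, b)` so every instant
belongs to exactly one interval. One random prompt is drawn uniformly per
interval (4/day for 10 days). A missed random prompt earns at most one
reminder, drawn uniformly between the point where its 15-minute response
window has lapsed and the interval end; deviation prompts get no reminders.
Random and deviation streams merge time-ordered with a minimum gap of 120 s
(the later prompt is delayed), and the blinded export carries no field from
which prompt kind could be recovered. Windows use a fixed UTC offset; a
daylight-saving transition mid-study is not handled (documented limitation).

Surveys ask emotion (13 fixed labels), intensity (integer 0–100), activity
(12 labels), company (8 child / 9 parent options), and — parents only —
parenting stress (0–100): 4 required answers for children, 5 for parents.
The 15-minute expiry is **exclusive**: an answer at exactly +15:00.000 is
rejected. At expiry, all-answered → *complete*, some-answered → *incomplete*,
none → *missed*. Some published summary tables print "content" and
"afraid/scared" for the instrument's "relaxed" and "scared" options; the
catalog keeps the instrument labels and the report layer applies an alias
map, since the instrument defines the options and reports merely relabel.

The response-behaviour model answers each survey fully with a per-role,
per-kind probability, partially with a small `partial_prob` (default 0.05),
and ignores it otherwise. Default probabilities (mothers .80/.74, fathers
.68/.65, children .45/.77 for random/deviation) reflect the engagement
pattern typical of family experience-sampling deployments: mothers most
responsive to random prompts, children least, children most responsive to
deviation prompts. Under these defaults a simulated 4-member × 10-day study
emits ~2 deviation prompts per member-day and pools to roughly 64% overall
engagement.

## Analytics

* **Engagement**: `100 × complete / received` per member, separately for
  random and deviation prompts and pooled; incomplete counts as
  non-complete (an alternate "started" rate is deliberately not the
  default). Zero-received cells are flagged undefined, never reported as 0%.
  Study-level engagement is offered both pooled over prompts and as the mean
  of member rates, since published overall rates rarely say which.
* **ICC(1)**: one-way random-effects intraclass correlation from the ANOVA
  mean squares, `(MSB − MSW)/(MSB + (k−1)·MSW)` with k = 2 children per
  family. Negative estimates are reported as computed (not clipped) and
  banded as "lack"; bands are lack/weak/moderate/strong/very strong at cut
  points .31/.51/.71/.91, and sibling scores are aggregated to a family mean
  iff ICC(1) ≥ .51. Zero total variance → flagged undefined.
* **Paired comparisons**: t = mean(d)/(sd(d)/√n) with sample SD, two-sided p
  from Student's t with n−1 df, and Cohen's d in the **paired d_z form**
  mean(d)/sd(d) — stated prominently because pooled-SD variants differ.
  Zero-variance nonzero differences are flagged (the effect size would be
  infinite) rather than reported numerically; a == b returns t = 0, p = 1.
  Interpretation follows the 0.20/0.50/0.80 small/medium/large benchmarks.
* **Endorsement tables**: per role × prompt kind, the percentage of answered
  surveys choosing each emotion/activity; columns sum to 100 within
  rounding; zero counts render as "-".
* **USE scores**: ease-of-use is the mean of the 9 retained ease items
  (items 7–8 excluded for poor factor loadings) and satisfaction the mean of
  its 4 items, all on the 1–7 Likert metric; missing items fall back to the
  available-item mean with a flag.
* **Correlations**: pairwise-complete Pearson r with `*`/`**` at p < .05/.01
  and `†` marking nonsignificant |r| > .50.

## Reproducibility and problem sizes

Every randomized stage takes an explicit seed; a run directory's manifest
(config hash, derived seeds, per-file SHA-256) suffices to reproduce it
byte-identically. The test suite and the acceptance script use the scales
the checks are defined at — 1,000 seeded scheduler days, 100 random streams
for the streaming/offline equivalence, 50 datasets per statistical oracle,
10,000 prompts for response-probability recovery, 20 sessions × 3 episodes
for detector sensitivity, and one full 4-member × 10-day study — which keep
a complete run in the low tens of seconds on a single CPU.

## Known limitations

No tonic/phasic deconvolution or per-artifact classification; no real-device
ingestion beyond the CSV dialect; no push delivery, time zones beyond a fixed
offset, or DST; the behaviour model is stationary (no day-of-study fatigue
or time-of-day effects); and the artifact model is symmetric and brief,
unlike some real motion-noise regimes.
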