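# edaprompt

Simulation and analysis toolkit for **EDA deviation-triggered experience
sampling** — ambulatory studies in which family members wear a wrist device
streaming electrodermal activity (EDA, skin conductance in µS at 4 Hz) while
a phone app issues brief emotion surveys both at stratified random times and
whenever the wearer's sympathetic arousal rises meaningfully above their
calibrated resting level.

It is written for researchers designing or evaluating such protocols: every
stage of the pipeline runs without any device or participant, against
synthetic signals with known ground truth, so the detector, the scheduler and
the analytics can be validated end to end before a single family is enrolled.

## What it implements

* **Synthetic EDA** (`edaprompt.synth`) — tonic level as a mean-reverting
  drift in the 0–2 µS resting range, biexponential skin-conductance responses
  (SCRs), ground-truth *arousal episodes* that multiply the tonic level by a
  known factor, and brief motion artifacts; plus a plain-text per-channel CSV
  dialect matching the wrist device's export format (`edaprompt.streams`).
* **Deviation trigger** (`edaprompt.deviation`) — a baseline is the mean EDA
  over a 3-minute calibration (720 samples at 4 Hz). During study hours,
  smoothed EDA is compared against `baseline × (1 + θ)` with operative
  threshold θ = 0.20 (configurable down to the 0.15 literature benchmark); a
  trigger fires after the signal holds at/above threshold for a sustain
  period, subject to a refractory interval and a cap of **4 deviation
  notifications per day**.
* **Prompt scheduler** (`edaprompt.scheduler`) — study hours are 16:00–20:00
  on weekdays and 10:00–18:00 on weekends, divided into 4 equal intervals
  with exactly one uniformly-timed random prompt per interval (4/day for 10
  days), one in-interval reminder for missed prompts, and a merged, blinded
  notification stream in which random and deviation prompts are
  indistinguishable.
* **Survey lifecycle** (`edaprompt.survey`) — the instrument (13 emotions,
  0–100 intensity, 12 activities, 8/9 company options, plus a parenting-stress
  slider for parents: 4 questions for children, 5 for parents), a strict
  15-minute response window, and the complete / incomplete / missed
  classification.
* **Analytics** (`edaprompt.analytics`) — engagement rates per member and
  prompt kind; one-way random-effects intraclass correlation
  `ICC(1) = (MSB − MSW) / (MSB + (k−1)·MSW)` with agreement bands at
  .31/.51/.71/.91 and sibling aggregation at the a-priori cutoff .51; paired
  t-tests with Cohen's d in the paired form d_z = mean(diff)/sd(diff);
  emotion/activity endorsement percentage tables; Pearson correlation tables;
  and USE questionnaire ease-of-use (items 7–8 excluded) and satisfaction
  subscale scores.
* **Pipeline + CLI** (`edaprompt.pipeline`, `edaprompt.cli`) — one config and
  one master seed reproduce a whole study byte-for-byte.

## Worked example

```bash
edaprompt simulate --config examples/demo_config.yaml --seed 1 --out run
```

simulates a two-parent/two-child family for 10 days and prints
`run written to run`. The run directory then contains the per-member streams,
trigger log, schedule, response log and reports. With seed 1:

```bash
$ python -m json.tool run/reports/summary.json
{
    "engagement_deviation_pooled_pct": 69.6203,
    "engagement_member_mean_pct": 63.5463,
    "engagement_pooled_pct": 64.0167,
    "engagement_random_pooled_pct": 61.25,
    "n_surveys": 239
}
```

Reading this: the four members received 239 surveys in total — 160 random
(4/day × 10 days × 4 members) plus 79 emitted deviation surveys (~2.0 per
member per day on average, the product of the 20% threshold, the refractory
period and the daily cap acting on the generated arousal episodes). 64.0%
of all surveys were fully completed within their 15-minute window (pooled
over members), 61.3% of random and 69.6% of deviation surveys — the direct
consequence of the role-specific response probabilities configured in the
demo roster. `run/reports/engagement.csv` breaks the same rates down per
member and kind, and `run/reports/endorsement_emotions.csv` shows which
emotions were endorsed, with `-` marking never-chosen options.

The same stages are available programmatically:

```python
from edaprompt import (MemberProfile, StudyDesign, simulate_member_session,
                       simulate_tonic, compute_baseline, detect_deviations)
from datetime import date

profile = MemberProfile(role="mother")
design = StudyDesign()
stream, truth = simulate_member_session(profile, design, date(2023, 5, 1), seed=7)
baseline = compute_baseline(simulate_tonic(profile, 180.0, seed=1), 0.0, 180.0)
triggers = detect_deviations(stream, baseline, design.deviation_cfg)
```

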