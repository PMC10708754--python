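# Demo study configuration: a two-parent, two-child family over 10 days.
# CLI flags (--seed, --days, --threshold, --cap) override these values.
design:
  n_days: 10
  n_intervals: 4
  survey_window_min: 15
  deviation:
    threshold_fraction: 0.20
    daily_cap: 4
roster:
  - member_id: mother
    role: mother
    tonic_mean_us: 1.1
    response_prob_random: 0.80
    response_prob_deviation: 0.74
  - member_id: father
    role: father
    tonic_mean_us: 1.3
    response_prob_random: 0.68
    response_prob_deviation: 0.65
  - member_id: child1
    role: child
    tonic_mean_us: 0.9
    response_prob_random: 0.45
    response_prob_deviation: 0.77
  - member_id: child2
    role: child
    tonic_mean_us: 0.95
    response_prob_random: 0.45
    response_prob_deviation: 0.77
master_seed: 1
start_date: 2023-05-01
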