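# Null preset: the walk-bout rate is constant over hours and days, so the
# timing of walks carries no information — any classifier should sit at
# chance on balanced instances.  Marginal walk rate matches the default.
n_participants: 41
n_days: 43
seed: 0
start_date: "2015-08-03"
missing_day_prob: 0.369
daily_bouts: 2.72
hourly_weights: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                 1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
                 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
dow_weights: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
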