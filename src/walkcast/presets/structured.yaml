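# Structured preset: walk bouts are strongly concentrated in three daily
# windows (commute, lunch, evening) on weekdays, so the hour-of-day and
# lag-history predictors carry real signal.  Used to demonstrate that the
# pipeline recovers predictability when it exists.
n_participants: 41
n_days: 43
seed: 0
start_date: "2015-08-03"
missing_day_prob: 0.369
daily_bouts: 2.8
hourly_weights: [0.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                 0.0, 1.0, 1.0, 0.0, 0.0, 0.0,
                 1.0, 0.0, 0.0, 0.0, 0.0, 0.0,
                 1.0, 1.0, 0.0, 0.0, 0.0, 0.0]
dow_weights: [1.3, 1.3, 1.3, 1.3, 1.3, 0.25, 0.25]
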