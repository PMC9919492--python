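# Default cohort preset: free-living adults wearing a wrist-band step counter
# for a 6-week study.  Calibrated so detected bouts/day ~ 2.6, mean bout
# length ~ 10.3 min, recorded time ~ 146 min/day, missing days ~ 36.9%.
n_participants: 41
n_days: 43
seed: 0
start_date: "2015-08-03"
missing_day_prob: 0.369
# daily_bouts is the expected Poisson *starts* per day; merging of
# overlapping/contiguous bouts makes detected bouts slightly fewer.
daily_bouts: 2.72
hourly_weights: [0.0, 0.0, 0.0, 0.0, 0.0, 0.1,
                 0.5, 1.2, 1.5, 0.8, 0.6, 0.9,
                 1.4, 1.0, 0.7, 0.6, 0.8, 1.3,
                 1.6, 1.1, 0.7, 0.4, 0.2, 0.1]
dow_weights: [1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0]
bout_duration: {family: lognormal, params: {mu: 2.09, sigma: 0.62, low: 5, high: 120}}
active_cadence: {family: normal, params: {mean: 100.0, sd: 15.0, low: 60, high: 180}}
background_cadence: {family: lognormal, params: {mu: 2.6, sigma: 0.9, low: 0, high: 59}}
background_minutes: {family: normal, params: {mean: 119.0, sd: 30.0, low: 0, high: 600}}
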