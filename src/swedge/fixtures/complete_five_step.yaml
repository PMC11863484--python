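# Complete five-step comparator scenario: 15 schools (3 per sequence),
# closed cohort of 27 pupils per school, 5 min effect on weekday MVPA with
# total SD 23 min, ICC 0.08, CAC 0.75, IAC 0.45, no background time trend.
design:
  kind: complete
  n_sequences: 5
allocation: [3, 3, 3, 3, 3]
sd_total: 23.0
icc: 0.08
cac: 0.75
iac: 0.45
cohort:
  kind: closed
  eligible_per_school: 27
  recruitment_rate: 1.0
effect: 5.0
baseline_mean: 100.0
trend:
  kind: none
alpha: 0.05
n_sims: 1000
master_seed: 20240901
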