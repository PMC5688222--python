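# Two-lever within-subjects discrimination: continuous (p=1.0) schedule on
# stimulus 1 -> response 1, partial (p=0.5) on stimulus 2 -> response 2.
# Model sections are optional; omitted keys take the package defaults.
protocol:
  name: ko_expl
  kind: two_lever
  schedules:
    1: [1, 1.0]
    2: [2, 0.5]
  acquisition_trials: 240
  extinction_trials: 40
  acquisition_block: 40
  extinction_block: 10
  n_runs: 50
  seed_base: 1
  max_same_type_run: 3

critic:
  kappa: 9.6
  tau: 10.0
  beta_m: 0.06
  beta_o: 0.10

actor:
  beta_sr: 0.105
  beta_er: 0.06
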