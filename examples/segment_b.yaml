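# CRM phase I dose finding (6 levels, toxicity target 0.25) gating a
# fixed 42-patient single-arm phase II at the selected dose, with an
# end-of-trial toxicity monitor at a 0.25 observed adverse-event rate.
segment: B
n_reps: 500
seed: 20230629
phase1:
  n1: 20
  skeleton: [0.05, 0.12, 0.25, 0.40, 0.55, 0.68]
  tox_target: 0.25
  prior_sd: 1.34
  start_dose: 3
  no_skip: true
phase2:
  n: 42
  orr0: 0.4
  alpha: 0.05
  tox_monitor_threshold: 0.25
scenario:
  tox: [0.02, 0.06, 0.12, 0.20, 0.35, 0.50]
  orr: [0.15, 0.30, 0.50, 0.60, 0.65, 0.67]
output:
  csv: segment_b_metrics.csv
  manifest: segment_b_manifest.json
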