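# Phase II single-arm trial (exact binomial, one-sided 0.05) gating a
# phase III RCT sized for 90% one-sided Fisher power at the phase II
# response estimate versus the historical 0.4, capped at 400 patients.
segment: A
n_reps: 1000
seed: 20230629
phase2:
  n2: 60
  orr0: 0.4
  orr1_alt: 0.6
  alpha: 0.05
phase3:
  alpha: 0.05
  target_power: 0.9
  max_total: 400
  sizing: exact
scenario:
  true_orr1: 0.6
  true_orr0: 0.4
enrollment:
  rate_phase_a: 4.0
  rate_phase_b: 10.0
  gap_months: 6.0
  followup_months_a: 6.0
  followup_months_b: 6.0
output:
  csv: segment_a_metrics.csv
  manifest: segment_a_manifest.json
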