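# Adaptive biomarker-enrichment phase II (three stages, two interim
# cutoff adaptations over the 0.1..0.9 grid, exact one-sided McNemar)
# gating a phase III RCT in the selected biomarker subgroup.
segment: C
n_reps: 1000
seed: 20230629
phase2:
  n2: 130
  cutoffs: [0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9]
  stage_fractions: [0.5, 0.25, 0.25]
  alpha: 0.05
  min_subgroup_pairs: 5
phase3:
  alpha: 0.05
  target_power: 0.9
  max_total: 400
scenario:
  orr0: 0.4
  slope: 4.0
  crossing: 0.6
output:
  csv: segment_c_metrics.csv
  manifest: segment_c_manifest.json
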