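# Example ibdqsp pipeline configuration (all fields optional; these are the
# package defaults at a reduced desk scale for a quick run).
seed: 1
out_dir: results
cohort_size: 400
population_size: 120

baseline:            # synthetic trial-report baseline law to match
  crp_median: 10.0   # mg/L
  crp_gsd: 2.5
  fcp_median: 600.0  # mg/kg
  fcp_gsd: 2.5
  kind: median_iqr   # or mean_sd | median_range
  tolerance: 0.15

calibration:
  enabled: true
  params: ["Kd:PF-04236921", "b_CRP"]
  maxfev: 40
  population_size: 40

trial:
  regimen_a: infliximab_induction   # 5 mg/kg IV weeks 0, 2, 6
  regimen_b: ustekinumab_6mgkg      # single 6 mg/kg IV dose
  horizon_days: 84.0

criterion: crp_below_3              # responder partition cutoff

solver:
  rtol: 1.0e-8
  atol: 1.0e-10

# per-drug antibody affinity overrides (nM), optional
# kd_nM:
#   infliximab: 0.05
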