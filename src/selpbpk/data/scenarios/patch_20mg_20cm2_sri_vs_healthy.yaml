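# Single-dose 20 mg / 20 cm2 transdermal patch worn 24 h: severe renal
# impairment versus healthy adults, ratio table over total and unbound
# exposure metrics.
name: patch_20mg_20cm2_sri_vs_healthy
population: sri
compare_to: healthy
metabolite_albumin_binding: true
regimen:
  route: transdermal
  dose: 20.0
  duration: 24.0
  interval: 24.0
  n_doses: 1
  patch:
    drug_load: 20.0
    area: 20.0
    wear_duration: 24.0
    release_model: first_order
    release_rate: 0.04
trial_design:
  n_per_trial: 8
  n_trials: 10
  seed: 20946
duration: 72.0
output_dir: results/patch_sri_vs_healthy
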