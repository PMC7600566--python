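# 24-h intravenous infusion of 8.37 mg selegiline in healthy adults,
# 10 virtual trials of 13 subjects (the clinical infusion study design).
name: iv_healthy_8.37mg
population: healthy
regimen:
  route: iv_infusion
  dose: 8.37
  duration: 24.0
  interval: 24.0
  n_doses: 1
trial_design:
  n_per_trial: 13
  n_trials: 10
  seed: 20946
duration: 48.0
output_dir: results/iv_healthy
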