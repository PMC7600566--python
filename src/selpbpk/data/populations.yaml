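# Population preset registry v1.
#
# Means for cardiac output, hepatic flow fraction, GFR ratio and plasma fu
# follow the published population physiology table for this model; CYP
# abundance means/CVs, phenotype frequencies, albumin levels and the
# impairment multipliers are this package's documented defaults (the source
# simulator's library is proprietary).  Abundances in pmol/mg microsomal
# protein; proteins in uM; cardiac output and flows in L/h; liver weight g;
# body weight kg; CVs are fractional.
#
# hepatic_flow_fraction reproduces the published hepatic blood flow means:
# healthy 350.19*0.2550 = 89.30; SRI 268.79*0.2672 = 71.82;
# CP-C 299.67*0.2365 = 70.88; adolescent 333.70*0.2685 = 89.59.
healthy:
  age_range: [20, 50]
  proportion_female: 0.0
  body_weight:
    male: {mean: 81.0, cv: 0.15}
    female: {mean: 66.0, cv: 0.15}
  cardiac_output: {mean: 350.19, cv: 0.17}
  hepatic_flow_fraction: 0.2550
  liver_weight: {mean: 1650.0, cv: 0.21}
  mppgl: {mean: 40.0, cv: 0.30}
  gfr_ratio: {mean: 0.99, cv: 0.17}
  hematocrit: 0.45
  macroglobulin:
    male: {mean: 3.95, cv: 0.177}
    female: {mean: 4.47, cv: 0.144}
  albumin: {mean: 624.0, cv: 0.06, age_slope_per_year: -1.0, age_ref: 35}
  cyp_abundance:
    CYP1A2: {mean: 52.0, cv: 0.45}
    CYP2A6: {mean: 42.0, cv: 0.55}
    CYP2B6: {mean: 17.0, cv: 0.60}
    CYP2C8: {mean: 24.0, cv: 0.55}
    CYP2C9: {mean: 73.0, cv: 0.45}
    CYP2C18: {mean: 2.5, cv: 0.50}
    CYP2C19: {mean: 14.0, cv: 0.60}
    CYP2D6: {mean: 8.0, cv: 0.45}
    CYP2E1: {mean: 61.0, cv: 0.40}
    CYP3A4: {mean: 137.0, cv: 0.40}
  phenotypes:
    CYP2D6:
      - {name: EM, frequency: 0.89, multiplier: 1.0}
      - {name: PM, frequency: 0.08, multiplier: 0.0}
      - {name: UM, frequency: 0.03, multiplier: 2.0}

geriatric:
  base: healthy
  age_range: [60, 85]
  cardiac_output: {mean: 318.0, cv: 0.17}
  gfr_ratio: {mean: 0.75, cv: 0.20}
  albumin: {mean: 600.0, cv: 0.06, age_slope_per_year: -1.0, age_ref: 35}

adolescent:
  base: healthy
  age_range: [12, 20]
  body_weight:
    male: {mean: 60.0, cv: 0.18}
    female: {mean: 54.0, cv: 0.18}
  cardiac_output: {mean: 333.70, cv: 0.17}
  hepatic_flow_fraction: 0.2685
  liver_weight: {mean: 1500.0, cv: 0.21}
  gfr_ratio: {mean: 1.05, cv: 0.17}

# Moderate renal impairment (GFR 30-60 mL/min/1.73 m2)
mri:
  base: healthy
  age_range: [40, 75]
  cardiac_output: {mean: 309.0, cv: 0.18}
  hepatic_flow_fraction: 0.2610
  gfr_ratio: {mean: 0.35, cv: 0.20}
  macroglobulin:
    male: {mean: 7.27, cv: 0.373}
    female: {mean: 8.21, cv: 0.219}
  albumin: {mean: 580.0, cv: 0.08, age_slope_per_year: -1.0, age_ref: 35}
  abundance_multipliers:
    CYP1A2: 0.65
    CYP2A6: 0.65
    CYP2B6: 0.62
    CYP2C8: 0.65
    CYP2C9: 0.65
    CYP2C18: 0.65
    CYP2C19: 0.65
    CYP2D6: 0.58
    CYP2E1: 0.70
    CYP3A4: 0.62

# Severe renal impairment (GFR < 30 mL/min/1.73 m2)
sri:
  base: healthy
  age_range: [40, 75]
  cardiac_output: {mean: 268.79, cv: 0.18}
  hepatic_flow_fraction: 0.2672
  gfr_ratio: {mean: 0.16, cv: 0.25}
  macroglobulin:
    male: {mean: 7.27, cv: 0.373}
    female: {mean: 8.21, cv: 0.219}
  albumin: {mean: 541.0, cv: 0.08, age_slope_per_year: -1.0, age_ref: 35}
  abundance_multipliers:
    CYP1A2: 0.35
    CYP2A6: 0.35
    CYP2B6: 0.36
    CYP2C8: 0.34
    CYP2C9: 0.34
    CYP2C18: 0.34
    CYP2C19: 0.34
    CYP2D6: 0.31
    CYP2E1: 0.40
    CYP3A4: 0.36

# Child-Pugh B hepatic cirrhosis
cp_b:
  base: healthy
  age_range: [40, 70]
  cardiac_output: {mean: 320.0, cv: 0.18}
  hepatic_flow_fraction: 0.2450
  liver_weight: {mean: 1450.0, cv: 0.21}
  gfr_ratio: {mean: 0.70, cv: 0.22}
  macroglobulin:
    male: {mean: 5.488, cv: 0.2388}
    female: {mean: 5.23, cv: 0.192}
  albumin: {mean: 450.0, cv: 0.10, age_slope_per_year: -1.0, age_ref: 35}
  abundance_multipliers:
    CYP1A2: 0.40
    CYP2A6: 0.45
    CYP2B6: 0.45
    CYP2C8: 0.45
    CYP2C9: 0.50
    CYP2C18: 0.45
    CYP2C19: 0.25
    CYP2D6: 0.30
    CYP2E1: 0.55
    CYP3A4: 0.45

# Child-Pugh C hepatic cirrhosis
cp_c:
  base: healthy
  age_range: [40, 70]
  cardiac_output: {mean: 299.67, cv: 0.18}
  hepatic_flow_fraction: 0.2365
  liver_weight: {mean: 1400.0, cv: 0.21}
  gfr_ratio: {mean: 0.47, cv: 0.25}
  macroglobulin:
    male: {mean: 5.488, cv: 0.2388}
    female: {mean: 5.23, cv: 0.192}
  albumin: {mean: 346.0, cv: 0.10, age_slope_per_year: -1.0, age_ref: 35}
  abundance_multipliers:
    CYP1A2: 0.30
    CYP2A6: 0.30
    CYP2B6: 0.30
    CYP2C8: 0.30
    CYP2C9: 0.35
    CYP2C18: 0.30
    CYP2C19: 0.05
    CYP2D6: 0.05
    CYP2E1: 0.40
    CYP3A4: 0.30
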