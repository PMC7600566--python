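# Built-in compound registry: selegiline (SEL) and its metabolites
# methamphetamine (MAP), desmethylselegiline (DMS) and amphetamine (AMP).
# Column names mirror the published model-input table. Units: molecular_weight
# g/mol; cl_iv / cl_renal L/h; vss L/kg; binding dissociation constants uM.
# percent entries are % of the parent's hepatic metabolic clearance routed
# through the named CYP to the named product ("OHAMP" is a tracked sink).
SEL:
  molecular_weight: 187.28
  log_p: 2.7
  compound_type: monoprotic_base
  pka: 7.44
  fu: 0.10
  b_p: 1.34
  distribution_model: full
  vss: 9.26
  cl_iv: 84.56
  cl_renal: 0.46
  binding:
    kd_macroglobulin: 2.2
    kd_albumin: 95.0
  metabolism:
    - {enzyme: CYP1A2, product: MAP, percent: 4.21}
    - {enzyme: CYP1A2, product: DMS, percent: 1.64}
    - {enzyme: CYP2A6, product: MAP, percent: 3.13}
    - {enzyme: CYP2A6, product: DMS, percent: 0.77}
    - {enzyme: CYP2B6, product: MAP, percent: 26.27}
    - {enzyme: CYP2B6, product: DMS, percent: 6.48}
    - {enzyme: CYP2C8, product: DMS, percent: 0.10}
    - {enzyme: CYP2C9, product: DMS, percent: 0.23}
    - {enzyme: CYP2C18, product: MAP, percent: 1.22}
    - {enzyme: CYP2C18, product: DMS, percent: 1.05}
    - {enzyme: CYP2C19, product: MAP, percent: 32.70}
    - {enzyme: CYP2C19, product: DMS, percent: 3.58}
    - {enzyme: CYP2D6, product: MAP, percent: 8.37}
    - {enzyme: CYP2D6, product: DMS, percent: 7.20}
    - {enzyme: CYP2E1, product: DMS, percent: 0.69}
    - {enzyme: CYP3A4, product: MAP, percent: 1.89}
    - {enzyme: CYP3A4, product: DMS, percent: 0.45}
MAP:
  molecular_weight: 149.23
  log_p: 2.07
  compound_type: monoprotic_base
  pka: 9.9
  fu: 0.85
  b_p: 1.487
  distribution_model: full
  vss: 7.14
  cl_iv: 20.0
  cl_renal: 8.74
  metabolism:
    - {enzyme: CYP2D6, product: AMP, percent: 40.0}
    - {enzyme: CYP2D6, product: OHAMP, percent: 60.0}
DMS:
  molecular_weight: 173.25
  log_p: 2.46
  compound_type: monoprotic_base
  pka: 9.8
  fu: 0.47
  b_p: 1.70
  distribution_model: minimal
  vss: 5.37
  cl_iv: 35.8
  cl_renal: 0.96
  metabolism:
    - {enzyme: CYP2A6, product: AMP, percent: 15.0}
    - {enzyme: CYP2B6, product: AMP, percent: 45.0}
    - {enzyme: CYP3A4, product: AMP, percent: 40.0}
AMP:
  molecular_weight: 135.2
  log_p: 1.8
  compound_type: monoprotic_base
  pka: 9.9
  fu: 0.84
  b_p: 1.35
  distribution_model: minimal
  vss: 5.29
  cl_iv: 20.0
  cl_renal: 8.04
  metabolism: []
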