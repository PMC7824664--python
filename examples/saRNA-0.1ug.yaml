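vaccine:
  name: saRNA-0.1ug
  rna_per_dose_ug: 0.1
  doses_per_person: 1
  utp_type: wildtype
  feasible_scale_l: 1.0
process:
  volume_l: 1.0
  titre_g_per_l: 5.0
  nominal_recovery: 0.56
  failure_rate: 0.05
  residual_loss_factor: 0.92521
  capacity_anchors:
  - volume_l: 1.0
    batches_per_year: 471.0
    batch_duration_h: 41.0
  - volume_l: 30.0
    batches_per_year: 444.0
    batch_duration_h: 48.2
cost:
  cleancap_price: 3000.0
  mod_utp_price: 4700.0
  labour_rate: 20.0
  qc_fraction: 0.5
  cleancap_per_g_rna: 1.0
  modutp_per_g_rna: 0.55
  materials_other_per_g: 2900.0
  consumables_per_batch_ref: 277949.0
  consumables_scale_exponent: 0.38869
  consumables_reference_volume: 30.0
  labour_hours_per_batch: 150.0
  capex_ref: 76100000.0
  capex_exponent: 0.503
  capex_reference_volume: 30.0
  depreciation_years: 10.0
  design_titre_g_per_l: 5.0
demand:
  annual_doses: 8000000000.0
  population: 7800000000.0
  doses_per_person: 2
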