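# Age-stratified drinking-water exposure parameters (US EPA exposure handbook
# conventions) and per-analyte oral reference doses used by the human-health
# risk stage. FOE is stored as a day-count fraction; the package evaluates
# 350/365 exactly and rounds only for display.
profiles:
  adult:
    dwi_L_per_day: 2.0
    bw_kg: 70.0
    ab: 1.0
    foe_days_per_year: 350
  child:
    dwi_L_per_day: 1.0
    bw_kg: 15.0
    ab: 1.0
    foe_days_per_year: 350
reference_doses:
  BPA: {kind: ADI, value_mg_per_kg_day: 0.05, provisional: false}
  HQ: {kind: ADI, value_mg_per_kg_day: 0.04, provisional: false}
  RE: {kind: TDI, value_mg_per_kg_day: 0.04, provisional: false}
  BQ: {kind: RfD, value_mg_per_kg_day: 0.097, provisional: true}
# Solid-phase extraction volumes behind the method's pre-concentration factor:
# 250 mL of sample processed, reconstituted in 0.5 mL (factor 500).
spe:
  sample_volume_mL: 250.0
  reconstitution_volume_mL: 0.5
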