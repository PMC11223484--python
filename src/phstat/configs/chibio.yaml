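# Small-scale (Chi.Bio-class) pH-stat PET hydrolysis scenario:
# 12 mL reaction, 1.2 g amorphous PET film in 1 cm x 1 cm squares,
# 3 mg enzyme / g PET, 100 mM sodium phosphate at pH 8, 65 degC,
# 1 M NaOH titrant, 0.1 pH tolerance, 72 h.
seed: 0
chemistry:
  pKw: 13.997
  initial_ph: 8.0
  species:
    - name: phosphate
      pKa: [2.15, 7.21, 12.33]
      charge_fully_protonated: 0
      concentration_M: 0.1
    - name: TPA
      pKa: [3.51, 4.46]
      charge_fully_protonated: 0
      concentration_M: 0.0
    - name: MHET
      pKa: [3.2]
      charge_fully_protonated: 0
      concentration_M: 0.0
kinetics:
  film:
    n_films: 35
    length_cm: 1.0
    width_cm: 1.0
    thickness_cm: 0.025
    density_g_per_cm3: 1.38
    repeat_unit_mass_g_per_mol: 192.17
  enzyme:
    loading_mg_per_g: 3.0
    surface_rate_constant: 7.5e-6
    deactivation_rate_per_h: 0.01
    mhet_fraction: 0.10
    mhet_conversion_rate_per_h: 0.3
    bhet_fraction: 0.0
plant:
  volume_mL: 12.0
  temperature_C: 65.0
  probe:
    noise_sd: 0.02
    resolution: 0.01
    accuracy_band: 0.1
  pump:
    nominal_dose_uL: 40.0
    dose_sd_uL: 10.0
controller:
  target_ph: 8.0
  tolerance: 0.1
  cycle_time_s: 90.0
  mode: base_only
  set_dose_volume_uL: 40.0
  titrant_concentration_M: 1.0
  max_added_volume_mL: 15.0
  pump_line: 1
schedule:
  duration_h: 72.0
  measure_interval_s: 30.0
  ui_report_interval_s: 30.0
  kinetics_dt_s: 10.0
  sample_events: []
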