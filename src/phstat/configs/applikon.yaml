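# Litre-class stirred-tank pH-stat PET hydrolysis scenario:
# 250 mL working volume, 25 g PET film in 2.5 cm x 2.5 cm squares,
# 3 mg enzyme / g PET, 100 mM sodium phosphate at pH 8, 65 degC,
# 4 M NaOH titrant, 0.05 pH tolerance, 72 h.
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
    n_films: 116
    length_cm: 2.5
    width_cm: 2.5
    thickness_cm: 0.025
    density_g_per_cm3: 1.38
    repeat_unit_mass_g_per_mol: 192.17
  enzyme:
    loading_mg_per_g: 3.0
    surface_rate_constant: 7.5e-6
    # constant 400 rpm Rushton agitation: more shear deactivation than the
    # intermittently stirred small-scale vials
    deactivation_rate_per_h: 0.016
    # MHET was not observed to accumulate at the litre scale under these
    # loadings; the intermediate channel is switched off here.
    mhet_fraction: 0.0
    mhet_conversion_rate_per_h: 0.3
    bhet_fraction: 0.0
plant:
  volume_mL: 250.0
  temperature_C: 65.0
  probe:
    noise_sd: 0.01
    resolution: 0.01
    accuracy_band: 0.05
  pump:
    nominal_dose_uL: 100.0
    dose_sd_uL: 5.0
controller:
  target_ph: 8.0
  tolerance: 0.05
  # the commercial in-control module re-evaluates faster than the 90 s
  # user cycle of the small-scale controller
  cycle_time_s: 30.0
  mode: base_only
  set_dose_volume_uL: 100.0
  titrant_concentration_M: 4.0
  max_added_volume_mL: 80.0
  pump_line: 1
schedule:
  duration_h: 72.0
  measure_interval_s: 30.0
  ui_report_interval_s: 30.0
  kinetics_dt_s: 10.0
  sample_events: []
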