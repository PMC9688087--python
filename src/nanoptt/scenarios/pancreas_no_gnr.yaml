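# Matched control for pancreas_ptt: the same world, beam and schedule but no
# nanoparticle load — the whole phantom is plain pancreas tissue (scattering
# dominated, mu_s' ~ 20/cm), diffusivity 0.14 mm^2/s.
name: pancreas_no_gnr
world: {volume_cm3: 4.0, pitch_mm: 0.25, material: pancreas}
beam:
  wavelength_nm: 808.0
  power_w: 2.1
  tip_diameter_mm: 0.3
  tip_position_mm: [0.0, 0.0, 0.0]
  direction: [0.0, 0.0, 1.0]
  emission_rate: 2.0e6
  duration_s: 120.0
  area_unit: mm2
transport: {n_histories: 2000000, max_steps: 1000000}
thermal: {alpha_mm2_s: 0.14, baseline_c: 26.0, heating: energy, dt_s: 1.0}
probes:
  - {name: hd2, position_mm: [0.0, 2.0, 0.0]}
  - {name: vd2, position_mm: [0.0, 0.0, 2.0]}
times_s: [10, 20, 30, 40, 50, 60, 70, 85, 100, 120]
threshold_c: 155.0
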