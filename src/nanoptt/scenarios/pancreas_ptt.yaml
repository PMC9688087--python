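# Interstitial 808 nm photothermal therapy of a nanorod-loaded pancreas tumor.
# A cubic 4 cm^3 pancreas phantom holds a 3 cm^3 spherical tumor centered on
# the fiber tip at the origin (the nominal sphere is wider than the cube, so
# it is clipped to the world box). The tumor is uniformly loaded with
# 12.5 ug/mL of 10 x 41 nm gold nanorods; their absorption channel is derived
# from the rod load (nano_absorption: from_gnr), with the tumor tissue itself
# keeping the plain-pancreas absorption coefficient. The pinned permittivity
# is the size-corrected 808 nm gold value of the study parameter set.
name: pancreas_ptt
world: {volume_cm3: 4.0, pitch_mm: 0.25, material: pancreas}
tumor: {volume_cm3: 3.0, center_mm: [0.0, 0.0, 0.0], material: tumor_gnr, clip: true}
gnr:
  diameter_nm: 10.0
  length_nm: 41.0
  concentration_ug_ml: 12.5
  host_material: tumor_gnr
  permittivity: [-24.718, 3.6581]
  nano_absorption: from_gnr
  tissue_mu_a_per_cm: 0.0388
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
thermal: {alpha_mm2_s: 0.16, baseline_c: 26.0, heating: energy, dt_s: 1.0}
probes:
  - {name: hd2, position_mm: [0.0, 2.0, 0.0]}
  - {name: vd2, position_mm: [0.0, 0.0, 2.0]}
times_s: [10, 20, 30, 40, 50, 60, 70, 85, 100, 120]
threshold_c: 155.0
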