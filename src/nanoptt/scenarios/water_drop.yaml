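# Calibration benchmark: a 0.1 mL drop of nanorod suspension (0.625 mg/mL)
# in a 24-well footprint (cylinder radius 7.75 mm -> depth ~0.53 mm),
# surface-illuminated from above through air by a collimated beam for 30 s.
# The collimator diameter is not part of the study parameter set; 2 mm is
# assumed. The reported quantity is the maximum surface-voxel temperature
# rise (probe at the drop surface under the beam).
name: water_drop
world: {volume_cm3: 4.0, pitch_mm: 0.25, material: air}
drop: {radius_mm: 7.75, z_range_mm: [-0.53, 0.0], material: water_gnr}
gnr:
  diameter_nm: 10.0
  length_nm: 41.0
  concentration_ug_ml: 625.0
  host_material: water_gnr
  permittivity: [-24.718, 3.6581]
  nano_absorption: from_gnr
beam:
  wavelength_nm: 808.0
  power_w: 2.1
  tip_diameter_mm: 2.0
  tip_position_mm: [0.0, 0.0, 2.0]
  direction: [0.0, 0.0, -1.0]
  emission_rate: 2.0e6
  duration_s: 30.0
  area_unit: mm2
transport: {n_histories: 200000, max_steps: 1000000}
thermal: {alpha_mm2_s: 0.146, baseline_c: 26.0, heating: energy, dt_s: 1.0}
probes:
  - {name: surface, position_mm: [0.0, 0.0, -0.1]}
times_s: [10, 20, 30]
threshold_c: 155.0
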