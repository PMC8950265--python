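geometry:
  r_chamber_outer_mm: 28.0
  chamber_area_mm2: 20.0
  r_membrane_mm: 28.5
  channel_hydraulic_diameter_mm: 0.5
  channel_length_mm: 10.0
  channel_area_mm2: 1.0
fluids:
- name: artificial_urine
  density_kg_per_m3: 1000.0
  viscosity_cP: 1.0
  matrix_factor: 1.3
- name: assay_buffer
  density_kg_per_m3: 1000.0
  viscosity_cP: 1.0
  matrix_factor: 1.0
- name: artificial_plasma
  density_kg_per_m3: 1000.0
  viscosity_cP: 1.0
  matrix_factor: 0.6
membranes:
- name: nc_0.2um
  pore_radius_um: 0.19999999999999998
  permeability_m2: 1.0e-14
  entry_pressure_Pa: 500.0
  thickness_um: 150.0
  wetted_area_mm2: 3.14
  contact_angle_rad: 0.0
  surface_tension_N_per_m: 0.072
- name: nc_0.45um
  pore_radius_um: 0.44999999999999996
  permeability_m2: 2.5e-14
  entry_pressure_Pa: 300.0
  thickness_um: 150.0
  wetted_area_mm2: 3.14
  contact_angle_rad: 0.0
  surface_tension_N_per_m: 0.072
study:
  rpms:
  - 750.0
  - 1000.0
  - 1250.0
  - 1500.0
  - 1750.0
  - 2000.0
  replicates: 4
  sample_volume_uL: 200.0
  graduation_spacing_mm: 1.0
noise:
  timing_sd_s: 0.05
  permeability_cv: 0.1
seed: 1
output_dir: results
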