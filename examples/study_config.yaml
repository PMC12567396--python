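geometry:
  area_cm2: 0.64
  donor_volume_ml: 1.0
  receptor_volume_ml: 12.0
well_mixed_diffusivity_cm2_per_h: 10000.0
layers:
- name: DC
  thickness_cm: 1.5625
  diffusivity_cm2_per_h: 10000.0
  initial_concentration_mg_per_cm3: 5.0
  n_elements: 4
- name: SC
  thickness_cm: 0.002
  diffusivity_cm2_per_h: 0.000149
  initial_concentration_mg_per_cm3: 0.0
  n_elements: 40
- name: RS
  thickness_cm: 0.098
  diffusivity_cm2_per_h: 0.0018
  initial_concentration_mg_per_cm3: 0.0
  n_elements: 60
- name: RC
  thickness_cm: 18.75
  diffusivity_cm2_per_h: 10000.0
  initial_concentration_mg_per_cm3: 0.0
  n_elements: 8
interfaces:
- index: 1
  partition: 4.84
  mode: equilibrium
- index: 2
  partition: 0.96
  mode: equilibrium
- index: 3
  partition: 0.111
  mode: finite
  transfer_cm_per_h: 0.043
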