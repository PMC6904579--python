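species: Lepidozona mertensii
family: Ischnochitonidae
double_curved: true
parameters:
  width: 0.1872
  length: 0.36
  fillet_front: 0.018
  fillet_side: 0.0144
  beta_deg: 50.0
  h1: 0.0864
  height: 0.252
  alpha_deg: 90.0
  hook_reach: 0.018
  tip_height_frac: 0.85
  back_inflection_frac: 0.4
  apex_shift_frac: 0.45
  under_bulge_frac: 0.06
  back_bulge_frac: -0.12
  shoulder_width_frac: 0.75
  shoulder_height_frac: 0.2
  crown_roundness: 1.0
expected:
  H_L:
  - 0.7
  - 0.85
  W_L:
  - 0.5
  - 0.63
  h1_H:
  - 0.28
  - 0.4
  overlap_ratio:
  - 0.15
  - 0.3
  alpha_deg:
  - 87.0
  - 98.0
  beta_deg:
  - 45.0
  - 55.0
  V:
  - 0.002
  - 0.008
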