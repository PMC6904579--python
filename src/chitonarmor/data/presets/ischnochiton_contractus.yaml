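species: Ischnochiton (Ischnochiton) contractus
family: Ischnochitonidae
double_curved: false
parameters:
  width: 0.24
  length: 0.5
  fillet_front: 0.025
  fillet_side: 0.02
  beta_deg: 45.0
  h1: 0.15
  height: 0.31
  alpha_deg: 100.0
  hook_reach: 0.04
  tip_height_frac: 0.803
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.1
  back_bulge_frac: 0.1
  shoulder_width_frac: 0.85
  shoulder_height_frac: 0.32
  crown_roundness: 1.0
expected:
  H_L:
  - 0.65
  - 0.78
  W_L:
  - 0.48
  - 0.6
  h1_H:
  - 0.42
  - 0.52
  overlap_ratio:
  - 0.22
  - 0.38
  alpha_deg:
  - 95.0
  - 106.0
  beta_deg:
  - 40.0
  - 50.0
  V:
  - 0.006
  - 0.018
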