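species: Ischnochiton (Haloplax) lentiginosus
family: Ischnochitonidae
double_curved: false
parameters:
  width: 0.242
  length: 0.55
  fillet_front: 0.0275
  fillet_side: 0.022
  beta_deg: 35.0
  h1: 0.1045
  height: 0.297
  alpha_deg: 130.0
  hook_reach: 0.022
  tip_height_frac: 0.924
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.1
  back_bulge_frac: 0.1
  shoulder_width_frac: 0.78
  shoulder_height_frac: 0.24
  crown_roundness: 1.0
expected:
  H_L:
  - 0.55
  - 0.7
  W_L:
  - 0.45
  - 0.57
  h1_H:
  - 0.3
  - 0.4
  overlap_ratio:
  - 0.25
  - 0.4
  alpha_deg:
  - 124.0
  - 135.0
  beta_deg:
  - 30.0
  - 40.0
  V:
  - 0.006
  - 0.018
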