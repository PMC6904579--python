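species: Radsia barnesii
family: Chitonidae
double_curved: false
parameters:
  width: 0.2772
  length: 0.66
  fillet_front: 0.033
  fillet_side: 0.0264
  beta_deg: 26.0
  h1: 0.1155
  height: 0.33
  alpha_deg: 110.0
  hook_reach: 0.0132
  tip_height_frac: 0.772
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.1
  back_bulge_frac: 0.1
  shoulder_width_frac: 0.85
  shoulder_height_frac: 0.32
  crown_roundness: 1.0
expected:
  H_L:
  - 0.5
  - 0.65
  W_L:
  - 0.42
  - 0.55
  h1_H:
  - 0.3
  - 0.4
  overlap_ratio:
  - 0.35
  - 0.5
  alpha_deg:
  - 105.0
  - 116.0
  beta_deg:
  - 21.0
  - 31.0
  V:
  - 0.008
  - 0.025
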