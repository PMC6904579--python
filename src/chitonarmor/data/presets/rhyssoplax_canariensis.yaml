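species: Rhyssoplax canariensis
family: Chitonidae
double_curved: false
parameters:
  width: 0.2166
  length: 0.57
  fillet_front: 0.02
  fillet_side: 0.015
  beta_deg: 28.0
  h1: 0.0912
  height: 0.2622
  alpha_deg: 115.0
  hook_reach: 0.0114
  tip_height_frac: 0.777
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.18
  back_bulge_frac: 0.05
  shoulder_width_frac: 0.88
  shoulder_height_frac: 0.27
  crown_roundness: 1.0
expected:
  H_L:
  - 0.5
  - 0.6
  W_L:
  - 0.4
  - 0.5
  h1_H:
  - 0.3
  - 0.4
  overlap_ratio:
  - 0.3
  - 0.4
  alpha_deg:
  - 110.0
  - 120.0
  beta_deg:
  - 20.0
  - 30.0
  V:
  - 0.005
  - 0.016
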