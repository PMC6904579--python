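species: Rhyssoplax jugosa
family: Chitonidae
double_curved: false
parameters:
  width: 0.266
  length: 0.7
  fillet_front: 0.035
  fillet_side: 0.028
  beta_deg: 23.0
  h1: 0.119
  height: 0.336
  alpha_deg: 112.0
  hook_reach: 0.014
  tip_height_frac: 0.771
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
  - 0.4
  - 0.5
  h1_H:
  - 0.3
  - 0.4
  overlap_ratio:
  - 0.4
  - 0.6
  alpha_deg:
  - 107.0
  - 118.0
  beta_deg:
  - 18.0
  - 28.0
  V:
  - 0.008
  - 0.025
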