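species: Chiton cumingsii
family: Chitonidae
double_curved: false
parameters:
  width: 0.315
  length: 0.75
  fillet_front: 0.0375
  fillet_side: 0.03
  beta_deg: 15.0
  h1: 0.1275
  height: 0.27
  alpha_deg: 120.0
  hook_reach: 0.01125
  tip_height_frac: 0.627
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.1
  back_bulge_frac: 0.1
  shoulder_width_frac: 0.85
  shoulder_height_frac: 0.32
  crown_roundness: 1.0
expected:
  H_L:
  - 0.38
  - 0.5
  W_L:
  - 0.42
  - 0.55
  h1_H:
  - 0.42
  - 0.52
  overlap_ratio:
  - 0.5
  - 0.65
  alpha_deg:
  - 115.0
  - 126.0
  beta_deg:
  - 10.0
  - 20.0
  V:
  - 0.008
  - 0.03
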