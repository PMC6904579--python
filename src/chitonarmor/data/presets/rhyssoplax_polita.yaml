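species: Rhyssoplax polita
family: Chitonidae
double_curved: false
parameters:
  width: 0.513
  length: 1.35
  fillet_front: 0.0675
  fillet_side: 0.054
  beta_deg: 21.0
  h1: 0.20925
  height: 0.6075
  alpha_deg: 117.0
  hook_reach: 0.027
  tip_height_frac: 0.781
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
  - 0.6
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
  - 112.0
  - 123.0
  beta_deg:
  - 16.0
  - 26.0
  V:
  - 0.05
  - 0.12
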