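species: Ischnochiton (Heterozona) fruticosus
family: Ischnochitonidae
double_curved: false
parameters:
  width: 0.253
  length: 0.55
  fillet_front: 0.0275
  fillet_side: 0.022
  beta_deg: 40.0
  h1: 0.11
  height: 0.308
  alpha_deg: 105.0
  hook_reach: 0.033
  tip_height_frac: 0.81
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.1
  back_bulge_frac: 0.1
  shoulder_width_frac: 0.78
  shoulder_height_frac: 0.24
  crown_roundness: 1.0
expected:
  H_L:
  - 0.6
  - 0.72
  W_L:
  - 0.45
  - 0.6
  h1_H:
  - 0.3
  - 0.4
  overlap_ratio:
  - 0.2
  - 0.35
  alpha_deg:
  - 100.0
  - 111.0
  beta_deg:
  - 35.0
  - 45.0
  V:
  - 0.006
  - 0.02
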