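species: Ischnochiton (Ischnoradsia) australis
family: Ischnochitonidae
double_curved: false
parameters:
  width: 0.26
  length: 0.52
  fillet_front: 0.026
  fillet_side: 0.0208
  beta_deg: 60.0
  h1: 0.1352
  height: 0.3536
  alpha_deg: 90.0
  hook_reach: 0.052
  tip_height_frac: 0.848
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.1
  back_bulge_frac: 0.1
  shoulder_width_frac: 0.78
  shoulder_height_frac: 0.26
  crown_roundness: 1.0
expected:
  H_L:
  - 0.7
  - 0.82
  W_L:
  - 0.5
  - 0.62
  h1_H:
  - 0.32
  - 0.44
  overlap_ratio:
  - 0.1
  - 0.25
  alpha_deg:
  - 85.0
  - 96.0
  beta_deg:
  - 55.0
  - 65.0
  V:
  - 0.008
  - 0.02
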