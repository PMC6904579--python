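description: 'Printed-prototype scale: a Rhyssoplax canariensis-class hook with h1/H
  = 0.5 and a broad crown, calibrated so that at base length L = 10 mm the inflection
  (embedded) height is 4.1 mm, matching the mechanical-test panels.'
parameters:
  width: 0.48
  length: 1.0
  fillet_front: 0.05
  fillet_side: 0.04
  beta_deg: 28.0
  h1: 0.356253
  height: 0.712506
  alpha_deg: 115.0
  hook_reach: 0.06
  tip_height_frac: 0.827
  back_inflection_frac: 0.55
  apex_shift_frac: 0.65
  under_bulge_frac: 0.1
  back_bulge_frac: 0.1
  shoulder_width_frac: 0.95
  shoulder_height_frac: 0.6
  crown_roundness: 1.0
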