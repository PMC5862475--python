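# Theophylline 12 mg/kg i.v., 2.5 kg rabbits. Calibrated: fu 0.8 -> 0.5,
# liver clearance 0.07 -> 0.04 (specific, per kg liver, referenced to total
# plasma concentration; the convention consistent with the reference AUCs).
id: theophylline_iv_12
description: Theophylline 12 mg/kg i.v., first-order hepatic clearance
body_weight: 2.5
compound:
  name: theophylline
  MW: 180.16
  logP: -0.02
  fu: 0.8
  pKa:
    - {value: 8.81, kind: acid}
  solubility: 8.3
clearance:
  gfr_fraction: 0.0
  hepatic_CL_specific: 0.07
  reference_concentration: total
protocol:
  route: iv_bolus
  dose: 12.0
  dose_unit: mg_per_kg
calibrated_overrides:
  compound.fu: 0.5
  clearance.hepatic_CL_specific: 0.04
t_end_min: 2880.0
output_step_min: 2.0
tags: [iv, hepatic]
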