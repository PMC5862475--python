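# Theophylline 15 mg/kg i.v., 3.15 kg New Zealand white rabbits.
id: theophylline_iv_15
description: Theophylline 15 mg/kg i.v. (3.15 kg animals)
body_weight: 3.15
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
  dose: 15.0
  dose_unit: mg_per_kg
calibrated_overrides:
  compound.fu: 0.5
  clearance.hepatic_CL_specific: 0.04
t_end_min: 2880.0
output_step_min: 2.0
tags: [iv, hepatic]
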