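# Inulin 60 mg/kg i.v. bolus, 2.85 kg rabbits; pure prediction (no
# calibration was applied to capture both the 40 and 60 mg/kg doses).
id: inulin_iv_60
description: Inulin 60 mg/kg i.v., dose-linearity pair (high dose)
body_weight: 2.85
compound:
  name: inulin
  MW: 5000.0
  logP: -4.0
  fu: 1.0
  size_class: large
  blood_plasma_ratio: 0.0
clearance:
  gfr_fraction: 1.0
protocol:
  route: iv_bolus
  dose: 60.0
  dose_unit: mg_per_kg
t_end_min: 360.0
tags: [iv, large_molecule, pore_limited, renal, dose_linearity]
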