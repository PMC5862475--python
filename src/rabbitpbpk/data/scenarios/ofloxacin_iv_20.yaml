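# Ofloxacin 20 mg/kg i.v.; mixed renal (GFR + tubular secretion) and
# hepatic elimination. Calibrated: hepatic clearance 0.5 and tubular
# secretion 0.1 L/min. Body weight not printed; default 2.5 kg used.
id: ofloxacin_iv_20
description: Ofloxacin 20 mg/kg i.v., combined renal/hepatic clearance
body_weight: 2.5
compound:
  name: ofloxacin
  MW: 361.37
  logP: -0.39
  fu: 0.77
  pKa:
    - {value: 6.05, kind: acid}
    - {value: 8.11, kind: base}
  solubility: 28.0
clearance:
  gfr_fraction: 1.0
  tubular_secretion_CL: 0.1
  hepatic_CL_firstorder: 0.5
protocol:
  route: iv_bolus
  dose: 20.0
  dose_unit: mg_per_kg
t_end_min: 720.0
tags: [iv, renal, hepatic, tubular_secretion]
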