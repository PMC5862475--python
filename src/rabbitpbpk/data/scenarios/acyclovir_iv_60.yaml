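# Acyclovir 60 mg/kg i.v.; renal (GFR + tubular secretion, ~70% of dose in
# urine) plus hepatic elimination. Tubular secretion 0.3 L/min; the hepatic
# first-order clearance (0.028 L/min) is chosen so the simulated fraction
# excreted in urine is ~0.7 (see docs/methods.md). Body weight not printed
# for the i.v. study; default 2.5 kg used.
id: acyclovir_iv_60
description: Acyclovir 60 mg/kg i.v., renal secretion + hepatic clearance
body_weight: 2.5
compound:
  name: acyclovir
  MW: 225.21
  logP: -1.56
  fu: 0.85
  pKa:
    - {value: 9.25, kind: acid}
    - {value: 2.27, kind: base}
  solubility: 1.6
clearance:
  gfr_fraction: 1.0
  tubular_secretion_CL: 0.3
  hepatic_CL_firstorder: 0.028
protocol:
  route: iv_bolus
  dose: 60.0
  dose_unit: mg_per_kg
t_end_min: 720.0
tags: [iv, renal, tubular_secretion, hepatic]
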