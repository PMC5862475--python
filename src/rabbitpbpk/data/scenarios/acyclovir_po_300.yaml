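# Acyclovir 300 mg/kg oral solution, 3.6 kg rabbits. Calibrated: gastric
# emptying time raised from 0.5 to 4.91 hr.
id: acyclovir_po_300
description: Acyclovir 300 mg/kg p.o. solution
body_weight: 3.6
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
  route: oral
  dose: 300.0
  dose_unit: mg_per_kg
  formulation: {kind: solution}
calibrated_overrides:
  protocol.GET_hr: 4.91
t_end_min: 2880.0
output_step_min: 2.0
tags: [oral, solution, renal, tubular_secretion]
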