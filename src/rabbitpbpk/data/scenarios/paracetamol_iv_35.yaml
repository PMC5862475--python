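# Paracetamol 35 mg/kg i.v., 3.17 kg rabbits. CYP-mediated hepatic
# clearance: Vmax 40 umol/L/min, Km 10 umol/L, enzyme concentration
# 1 umol/L.
id: paracetamol_iv_35
description: Paracetamol 35 mg/kg i.v., saturable hepatic metabolism
body_weight: 3.17
compound:
  name: paracetamol
  MW: 151.16
  logP: 0.46
  fu: 0.9
  pKa:
    - {value: 9.38, kind: acid}
  solubility: 14.0
clearance:
  gfr_fraction: 0.0
  enzymes:
    - {Vmax: 40.0, Km: 10.0, E: 1.0}
protocol:
  route: iv_bolus
  dose: 35.0
  dose_unit: mg_per_kg
t_end_min: 720.0
tags: [iv, hepatic, michaelis_menten]
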