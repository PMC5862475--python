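# Paracetamol 50 mg rapidly disintegrating tablet; dissolution time 0.25
# min from the formulation literature, first-order shape.
id: paracetamol_po_rapid
description: Paracetamol 50 mg p.o. rapidly disintegrating tablet
body_weight: 2.5
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
  route: oral
  dose: 50.0
  dose_unit: mg
  formulation: {kind: rapid_tablet, DT: 0.25, DS: 1.0}
t_end_min: 1440.0
tags: [oral, tablet, hepatic, michaelis_menten]
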