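# Paracetamol 50 mg conventional tablet; hypothesized typical DT 240 min
# as the prediction default. The calibrated DT/DS are not printed in the
# main text; DT 100 min (faster than the 240 min default, slower than the
# rapid tablet, in the direction the data indicate) is the packaged choice.
id: paracetamol_po_conventional
description: Paracetamol 50 mg p.o. conventional tablet
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
  formulation: {kind: conventional_tablet, DT: 240.0, DS: 1.0}
calibrated_overrides:
  protocol.formulation.DT: 100.0
t_end_min: 1440.0
tags: [oral, tablet, hepatic, michaelis_menten]
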