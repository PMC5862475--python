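# Theophylline 200 mg oral conventional tablet, 3.15 kg rabbits.
# Calibrated: GET 1.66 hr, dissolution time 10 min (values inside the
# literature ranges).
id: theophylline_po_200
description: Theophylline 200 mg p.o. conventional tablet
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
  route: oral
  dose: 200.0
  dose_unit: mg
  formulation: {kind: conventional_tablet, DT: 240.0, DS: 1.0}
calibrated_overrides:
  compound.fu: 0.5
  clearance.hepatic_CL_specific: 0.04
  protocol.GET_hr: 1.66
  protocol.formulation.DT: 10.0
t_end_min: 4320.0
output_step_min: 2.0
tags: [oral, tablet, hepatic]
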