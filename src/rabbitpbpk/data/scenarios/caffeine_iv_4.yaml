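# Caffeine 4 mg/kg i.v. bolus, 3.5 kg rabbits; hepatically metabolized
# (saturable CYP process). Calibrated: fu 0.7 -> 0.8, Km 400 -> 300 umol/L.
# Vmax is not printed in the main text; 34 umol/L/min is back-derived from
# the reference optimized exposure via CL = Dose/AUC (see docs/methods.md).
id: caffeine_iv_4
description: Caffeine 4 mg/kg i.v., hepatic (enzymatic) clearance validation
body_weight: 3.5
compound:
  name: caffeine
  MW: 194.19
  logP: -0.07
  fu: 0.7
  solubility: 21.6
clearance:
  gfr_fraction: 0.0
  enzymes:
    - {Vmax: 34.0, Km: 400.0, E: 1.0}
protocol:
  route: iv_bolus
  dose: 4.0
  dose_unit: mg_per_kg
calibrated_overrides:
  compound.fu: 0.8
  clearance.enzymes.0.Km: 300.0
t_end_min: 1440.0
tags: [iv, hepatic, michaelis_menten]
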