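# Inulin 200 mg/kg i.v. bolus, 2.5 kg rabbit; plasma + five tissues observed.
# Inulin is the GFR probe: cleared solely by glomerular filtration, confined
# to plasma + interstitium (pore-limited large molecule, no RBC uptake).
# Calibrated adjustments: GFR_specific 0.6 -> 0.8 L/min/kg kidney, skin
# hydraulic conductivity raised, lung interstitial fraction raised.
id: inulin_iv_200
description: Inulin 200 mg/kg i.v., multi-tissue GFR validation
body_weight: 2.5
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
  dose: 200.0
  dose_unit: mg_per_kg
calibrated_overrides:
  physiology.GFR_specific: 0.8
  physiology.organs.skin.hydraulic_conductivity: 1.5e-4
  physiology.organs.lung.fraction_interstitial: 0.30
t_end_min: 360.0
tags: [iv, large_molecule, pore_limited, renal]
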