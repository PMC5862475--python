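# Default rabbit physiology (2.5 kg reference animal).
#
# Values are assembled from standard open physiology compilations
# (Brown-et-al.-style reference tables and common laboratory-animal
# handbooks): organ volumes and perfusion for a ~2.5 kg rabbit, GIT
# geometry/pH/transit for the rabbit gut. Every value is a default and can
# be overridden from a user configuration document.
#
# Units: volumes L, specific blood flow L/min per kg organ, lengths/radii
# cm, transit times min, GFR_specific L/min per kg kidney, GET hr.
# The liver's specific_blood_flow is the hepatic-artery share; portal
# organs (stomach, small/large intestine, spleen, pancreas) drain into the
# liver through the portal vein.
body_weight: 2.5
haematocrit: 0.36
GFR_specific: 0.6
arterial_volume: 0.04
venous_volume: 0.09
GET_hr: 0.5
organs:
  - {name: lung,            volume: 0.017,  specific_blood_flow: 23.7,
     fraction_vascular: 0.15, fraction_interstitial: 0.18, fraction_cellular: 0.67,
     water_fraction: 0.80, lipid_fraction: 0.01, protein_fraction: 0.15}
  - {name: heart,           volume: 0.006,  specific_blood_flow: 2.667,
     fraction_vascular: 0.10, fraction_interstitial: 0.10, fraction_cellular: 0.80,
     water_fraction: 0.75, lipid_fraction: 0.03, protein_fraction: 0.17}
  - {name: brain,           volume: 0.010,  specific_blood_flow: 1.2,
     fraction_vascular: 0.03, fraction_interstitial: 0.17, fraction_cellular: 0.80,
     water_fraction: 0.77, lipid_fraction: 0.11, protein_fraction: 0.10}
  - {name: muscle,          volume: 1.2,    specific_blood_flow: 0.0833,
     fraction_vascular: 0.02, fraction_interstitial: 0.10, fraction_cellular: 0.88,
     water_fraction: 0.76, lipid_fraction: 0.02, protein_fraction: 0.17}
  - {name: bone,            volume: 0.28,   specific_blood_flow: 0.107,
     fraction_vascular: 0.03, fraction_interstitial: 0.10, fraction_cellular: 0.87,
     water_fraction: 0.40, lipid_fraction: 0.10, protein_fraction: 0.30}
  - {name: skin,            volume: 0.28,   specific_blood_flow: 0.107,
     fraction_vascular: 0.02, fraction_interstitial: 0.35, fraction_cellular: 0.63,
     water_fraction: 0.65, lipid_fraction: 0.10, protein_fraction: 0.25}
  - {name: fat,             volume: 0.12,   specific_blood_flow: 0.0833,
     fraction_vascular: 0.02, fraction_interstitial: 0.14, fraction_cellular: 0.84,
     water_fraction: 0.15, lipid_fraction: 0.80, protein_fraction: 0.05}
  - {name: liver,           volume: 0.100,  specific_blood_flow: 0.25,
     fraction_vascular: 0.10, fraction_interstitial: 0.16, fraction_cellular: 0.74,
     water_fraction: 0.72, lipid_fraction: 0.05, protein_fraction: 0.20}
  - {name: kidney,          volume: 0.0175, specific_blood_flow: 4.571,
     fraction_vascular: 0.10, fraction_interstitial: 0.20, fraction_cellular: 0.70,
     water_fraction: 0.78, lipid_fraction: 0.03, protein_fraction: 0.17}
  - {name: spleen,          volume: 0.0015, specific_blood_flow: 2.667,
     fraction_vascular: 0.17, fraction_interstitial: 0.15, fraction_cellular: 0.68,
     water_fraction: 0.78, lipid_fraction: 0.02, protein_fraction: 0.18}
  - {name: pancreas,        volume: 0.003,  specific_blood_flow: 1.0,
     fraction_vascular: 0.05, fraction_interstitial: 0.12, fraction_cellular: 0.83,
     water_fraction: 0.72, lipid_fraction: 0.10, protein_fraction: 0.16}
  - {name: stomach,         volume: 0.012,  specific_blood_flow: 0.667,
     fraction_vascular: 0.03, fraction_interstitial: 0.10, fraction_cellular: 0.87,
     water_fraction: 0.75, lipid_fraction: 0.04, protein_fraction: 0.17}
  - {name: small_intestine, volume: 0.060,  specific_blood_flow: 1.0,
     fraction_vascular: 0.04, fraction_interstitial: 0.15, fraction_cellular: 0.81,
     water_fraction: 0.75, lipid_fraction: 0.04, protein_fraction: 0.17}
  - {name: large_intestine, volume: 0.040,  specific_blood_flow: 0.625,
     fraction_vascular: 0.04, fraction_interstitial: 0.15, fraction_cellular: 0.81,
     water_fraction: 0.75, lipid_fraction: 0.04, protein_fraction: 0.17}
git:
  - {name: stomach,     length: 10,  radius: 2.5, pH: 1.9, transit_time: 30,  ESAEF: 1.0}
  - {name: si_proximal, length: 150, radius: 0.5, pH: 6.5, transit_time: 90,  ESAEF: 10.0}
  - {name: si_distal,   length: 150, radius: 0.5, pH: 7.2, transit_time: 120, ESAEF: 5.0}
  - {name: caecum,      length: 40,  radius: 1.5, pH: 6.0, transit_time: 300, ESAEF: 1.5}
  - {name: colon,       length: 90,  radius: 0.8, pH: 6.6, transit_time: 480, ESAEF: 1.5}
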