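# Methods

## Scope and units

`rabbitpbpk` simulates whole-body disposition of small and large molecules
in the rabbit after i.v. bolus, i.v. infusion, or oral administration.
Package-wide units: amounts in µmol, volumes in L, time in min,
concentrations in µmol/L; doses in mg (or mg/kg) are converted through the
molecular weight at the boundary. Organ density is taken as 1 kg/L, so organ
weight (kg) equals organ volume (L).

## Body model

The default rabbit is a 2.5 kg animal with 14 organs (lung, heart, brain,
muscle, bone, skin, fat, liver, kidney, spleen, pancreas, stomach, small
and large intestine), arterial and venous whole-blood pools, haematocrit
0.36, and a specific glomerular filtration rate of 0.6 L/min per kg kidney.
Blood circulates venous pool → lung → arterial pool → systemic organs;
stomach, intestines, spleen and pancreas drain into the liver through the
portal vein, so venous return recomposes the cardiac output (~0.40 L/min)
identically — the network asserts this to 1e-6 relative at load time.

Values come from standard open physiology compilations for the rabbit
(organ volumes/perfusion in the style of the familiar reference tables,
GIT dimensions and pH from laboratory-animal handbooks). They are defaults,
not measurements of any specific study animal: every value can be
overridden from a user document, partial organ/segment lists merge against
the defaults by name, and the resolved table can be exported with per-value
provenance (default vs user). Other species are structurally possible but
no other default file ships.

Body-weight scaling is linear (exponent 1) in organ and blood-pool volumes;
specific flows (L/min/kg organ), sub-compartment fractions, GIT pH and
transit times, and GFR_specific are weight-invariant. The case studies span
2.5–3.6 kg, a ±25% range around the reference where allometric curvature is
negligible; scaling round-trips to 1e-12.

## Distribution

Each organ divides into vascular plasma, red blood cells, interstitium and
cells, with fractions summing to one (overriding one fraction rebalances
the cellular remainder).

Small molecules: the plasma↔interstitial step is treated as flow-limited
(exchange clearance = 5 × organ blood flow; the factor only needs to be
"fast relative to flow" and results are insensitive to it), leaving the
permeability barrier at the cell membrane: flux
`P·SA·(fu·C_int − fu·C_cell/Kp_cell)`, with a nominal exchange area of
100 dm² per L tissue (scalable per organ). `Kp_cell` is chosen so the
whole-tissue partition reproduces the calculated `Kp` at equilibrium:
`Kp_cell = (Kp − f_vasc − f_int)/f_cell`, floored at 1e-6 for very
hydrophilic compounds.

`Kp = f_water + f_lipid·10^logP + f_protein·(1/fu − 1)` is a deliberately
simple monotone composition model — the water term carries the aqueous
share, the lipid term octanol-like partitioning, the protein term mirrors
plasma binding into tissue protein. It is *not* a reimplementation of any
proprietary distribution model; per-organ `kp_overrides` exist precisely so
externally computed coefficients can be injected. Membrane permeability is
a two-parameter semi-empirical law
`P = 4e-5 dm/min · 10^(0.5·logP) · sqrt(300/MW)`, anchored so a neutral
300 g/mol compound of logP ≈ 0.5 absorbs from the proximal small intestine
with a half-time of tens of minutes (typical jejunal effective
permeabilities ~1e-4 cm/s scale); a `permeability_override` is available.
Charge enters only as a Henderson–Hasselbalch neutral-fraction multiplier
on GIT absorption at segment pH.

Red blood cells carry drug at a fixed RBC:plasma ratio (default 1,
first-order equilibration at 1 min⁻¹; advection carries both streams).
Large molecules set the ratio to 0 (plasma-confined), exchange with the
interstitium through a single pore-limited term
`K·SA·(C_p − C_int)` (default hydraulic conductivity 3e-5 L/min/dm²), have
no cellular uptake, and refuse oral protocols.

## GIT and formulations

Five luminal segments (stomach, proximal/distal small intestine, caecum,
colon) each carry a solid and a dissolved pool. Transit is first-order; the
stomach empties at `1/(GET·60)` with GET defaulting to 0.5 hr and
overridable per protocol. Solutions are instantaneously available dissolved
in the stomach. Tablets dissolve by the Weibull law with DT = time to 50%
dissolved, implemented as the time-dependent hazard
`h(t) = ln2·DS·t^(DS−1)/DT^DS` (evaluated at max(t, 1e-6) to keep DS < 1
finite at the origin); solids keep dissolving while they transit.
Absorption from each segment is `P·f_neutral(pH)·ESA·C_lumen` over the
cylindrical surface scaled by the effective surface area enhancement factor
(ESAEF: folds/villi/microvilli; default 10/5 in the proximal/distal small
intestine), and the absorbed flux enters the gut-wall organ's vascular
plasma, giving a first-pass route through the portal vein. Colon outflow
accumulates in a faeces sink. Default conventional-tablet DT is 240 min.
Solubility is carried as a compound property but does not limit dissolution
(no particle-size or saturation model).

## Elimination

All clearances act on the eliminating organ's vascular-plasma
concentration. Filtration is always unbound:
`gfr_fraction · GFR_specific · m_kidney · fu · C_p` → urine; "GFR 100%"
means `gfr_fraction = 1`. Tubular secretion and first-order hepatic
clearance are linear in a reference concentration selectable as unbound
(default) or total plasma; hepatic first-order clearance may be given in
absolute L/min or per kg liver (L/min/kg), the latter scaling with animal
size. The packaged theophylline scenarios use the per-kg-liver form with
total-plasma reference: that is the only reading of the reported
first-order values ("0.07 → 0.04") consistent with the reference AUC table
across both body weights and the oral study (1.05–1.74-fold agreement,
versus 3–4-fold under absolute/unbound readings). Enzymatic metabolism is
Michaelis–Menten, `V_liver · Vmax · E · C/(Km + C)` with the enzyme
concentration E a dimensionless multiplier normalized to 1 µmol/L, so the
plateau is `V_liver·Vmax·E`. Metabolites are a sink, not simulated species.

## Case-study parameterization

Each scenario carries a "predicted" layer (literature physicochemistry,
default physiology) and calibrated overrides. Where a study's inputs are
not recoverable, the packaged choice is documented here:

- caffeine: Vmax 34 µmol/L/min back-derived once from the optimized
  exposure via CL = Dose/AUC at low saturation (the study's own Vmax is
  not recoverable); Km 400→300 µmol/L and fu 0.7→0.8 are the calibrated
  deltas.
- acyclovir: tubular secretion 0.3 L/min; the hepatic first-order
  clearance (0.028 L/min) was set so the simulated urinary recovery is
  ~70% of dose, the quantity the original calibration targeted.
- paracetamol conventional tablet: the calibrated dissolution time is not
  recoverable; DT 100 min (slower than the rapid tablet, faster than the
  240 min default, the direction the data indicate) with DS 1.
- inulin: MW 5000 g/mol, fu 1, plasma-confined large molecule; calibrated
  GFR_specific 0.6→0.8 L/min/kg kidney, skin hydraulic conductivity ×5,
  lung interstitial fraction 0.18→0.30 (the latter two adjustments are
  directional, their magnitudes being package choices).
- ofloxacin: hepatic 0.5 and secretion 0.1 L/min as reported; under this
  flow network those values yield ~32% urinary recovery, short of the
  70–90% the original data show — kept as reported and noted as a known
  inconsistency.

## Numerics

LSODA integration at rtol 1e-8, atol 1e-10 µmol (mass-balance closure at
the 0.1%-of-dose acceptance level needs tight tolerances; measured
residuals are ~1e-14). The output grid is the requested uniform grid
augmented with 60 geometrically spaced points over the first 30 min so the
venous mixing transient after a bolus is resolved — without this, the
trapezoidal AUC of an i.v. profile is biased high by several percent.
Concentrations are floored at −1e-9 and clipped to zero (excursions are
recorded in metadata). AUC uses linear trapezoids with optional log-linear
terminal extrapolation from the last three positive points; Cmax ties
return the earlier time. Sensitivity uses one-sided +10% perturbations (one
extra run per parameter, matching the one-at-a-time definition); the
coefficients are absolute difference quotients, so squared-coefficient
rankings are unit-dependent by construction, and a normalized variant is an
opt-in flag. Calibration minimizes Σ(log C_obs − log C_sim)² with bounded
trust-region least squares from the nominal point plus Latin-hypercube
starts (deterministic per seed); parameters whose loss stays flat (<1e-6
relative) across their bounds are flagged unidentifiable rather than
"estimated".

## Synthetic data and what the tests show

The observed-data generator samples a simulated truth at given times and
applies multiplicative lognormal noise, `σ = sqrt(log(1+CV²))`, CV 15% by
default — emulating assay noise on digitized concentration points. It does
not emulate inter-animal variability, sampling-time error, assay limits of
quantification, or model misspecification; parameter-recovery results
therefore demonstrate estimator correctness and identifiability under the
model, not robustness to structural error in real data. The recovery
battery (one identifiable free parameter per case-study template, 20 noisy
replicates of 8 samples each, two optimizer starts) asks the median
recovered/true ratio to stay within [0.8, 1.25].

Closed-form oracles run on reductions: AUC = Dose/CL is checked with a
low-extraction compound (CL = 3e-4 L/min) because with clearance inside an
organ the venous AUC carries an arteriovenous offset Dose/Q_organ — the
closed form is exact only in the extraction→0 limit; the mono-exponential
one-compartment reduction uses 500 L/min/kg perfusion plus a permeability
override so the whole body collapses to one well-mixed volume whose k =
CL/V_eff follows from the parameters alone.

## Known limitations

- Simulated exposure for the inulin 40/60 mg/kg studies runs ~2.6–2.8-fold
  above the observed AUCs while the 200 mg/kg study agrees within 1.3-fold;
  the two source studies imply mutually inconsistent inulin clearances
  under any single kidney weight, so one of the two dose groups must drift.
- Acyclovir oral exposure overshoots (~3.5-fold): the absorbed fraction
  under the generic permeability law exceeds the low oral bioavailability
  this compound shows in vivo. A `permeability_override` fit to absorption
  data would close the gap; none is shipped because no such measurement is
  packaged.
- Tissue (as opposed to plasma) AUCs for the inulin study depend mainly on
  vascular + interstitial volume fractions; lung, with its large vascular
  fraction, overshoots the observed exposure ~3-fold.
- No enterohepatic recirculation, lymph flow, transporter kinetics beyond
  a lumped secretion clearance, metabolite kinetics, or inhalation/dermal
  routes. The two-pore formalism is collapsed to a single hydraulic
  conductivity per organ.
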