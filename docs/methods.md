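# Methods

## Model structure

The kinetic model is a generic 14-compartment, flow-limited (perfusion-
limited) whole-body description: liver, GI tract, fat, muscle, skin, bone,
brain, heart, kidney, lung, spleen, venous blood, arterial blood, and a
rest-of-body remainder.  Each perfused tissue T obeys

    dA_T/dt = Q_T · (C_art − C_T / Kp_T)

with A amounts (µmol), Q blood flows (L/h), C concentrations (µM) and
Kp the tissue:plasma partition coefficient.  The lung sits in series with
the total cardiac output between the venous and arterial pools.  Gut and
spleen effluents drain into the liver (portal vein), whose outflow is the
hepatic artery plus portal flow.

An oral dose (mg/kg bw, converted to µmol via the molecular weight and
body weight) enters the gut lumen at t = 0 and is absorbed by a
first-order process (kₐ, default 1 h⁻¹) delivered entirely to the liver.

Elimination:

* **Liver** — microsomal and cytosolic Michaelis–Menten hydrolysis to
  BCP, each acting on the unbound concentration in the blood leaving the
  liver, C_u = fup · C_liver / Kp_liver, with whole-liver capacities
  V_scaled · V_liver (µmol/h).
* **Blood** — plasma-enzyme Michaelis–Menten hydrolysis on the unbound
  blood concentration, with whole-blood capacity split over the venous and
  arterial pools in proportion to their volumes.
* **Kidney** — passive glomerular filtration of unbound venous blood at a
  fixed species rate (0.078 L/h rat, 6.7 L/h human).

Assumptions: perfusion-limited distribution (no membrane barriers),
blood:plasma ratio 1 (predictions are reported as blood concentrations
while partitioning is plasma-referenced — a documented simplification),
instantaneous well-stirred compartments, and no inhibition feedback of
profenofos on its own esterase-mediated clearance.

### BCP / BCP-glucuronide sub-model (rat)

The only published in vivo kinetic data for profenofos in rats are urinary
excretions of conjugated BCP, so the rat model can carry an evaluation
sub-model: BCP is formed mole-for-mole wherever parent is hydrolysed
(liver and blood), distributed over the same 14 compartments with its own
estimated Kp set and unbound fraction, and glucuronidated exclusively in
the liver (Michaelis–Menten on unbound BCP; package defaults Kₘ 300 µM,
V 15 nmol/min/mg microsomal protein — phenol-type glucuronidation
values, user-overridable).  The conjugate occupies a single central volume
(computed from its estimated Kp set) and is filtered to urine
(GFR · fu_conjugate).  Glucuronidation is BCP's only exit, so the
late-time urinary plateau equals the total fraction of the dose
metabolised (a tested mole-balance identity).  The human model omits the
sub-model.

## Partition coefficients

Kp values are estimated from tissue composition: each tissue is a mixture
of water, neutral lipid and phospholipid (phospholipid treated as a 30:70
lipid:water hybrid).  The neutral species partitions into lipid with the
octanol:water coefficient (vegetable-oil:water for adipose, from the
standard regression log D_vo = 1.115·logKow − 1.35); ionization at pH 7.4
follows Henderson–Hasselbalch for acids and bases.  Plasma binding enters
as fup, and the tissue unbound fraction is derived from fup assuming
interstitial binding proteins at half the plasma concentration.
Profenofos has no ionizable group near physiological pH and is treated as
neutral; the speciation path is unit-tested with acid/base test
compounds.  Per-tissue user overrides take precedence over estimates and
are provenance-tagged.  The composition table ships as a versioned CSV.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| kₐ | 1/h | 1.0 | stated first-order oral absorption |
| fup (profenofos) | – | 0.02 | lipophilicity-based estimate (logKow 4.44, neutral); not a measured value |
| blood:plasma ratio | – | 1.0 | not stated; documented simplification |
| scaling factors | mg/g | 35 / 80.7 / 550 | microsomal, cytosolic protein per g liver; mg plasma per g blood |
| fu incubation | – | 1.0 each | binding in incubations argued negligible; configurable; in vivo Kₘ = in vitro Kₘ · fu_inc |
| renal clearance | L/h | 0.078 rat / 6.7 human | glomerular filtration of unbound blood |
| Kₘ, V per matrix | µM, nmol/min/mg | measured table | drive all clearances after scaling |
| BMR | – | 0.10 | 10-percentage-point inhibition benchmark |
| n_boot | – | 200 | bootstrap size for BMDL (warning below 50) |

The plasma scaling basis ("550 mg plasma per g blood" applied to rates per
mg plasma) is taken literally; whether plasma mass or plasma-protein mass
is the correct basis is ambiguous, and the factor is configurable through
`ScalingFactors`.

## Numerical choices

* Stiff integration with LSODA (BDF fallback available), rtol 1e-8 /
  atol 1e-10, dense output; a Rosenbrock-class solver would serve
  equally, and a tolerance-halving test verifies the unbound Cmax is
  converged to < 0.1%.
* Unbound Cmax = fup × the venous-blood peak, refined between output
  points by a bounded scalar search on the dense solution.
* Dose → Cmax map: 40 log-spaced doses over 10⁻⁴–10³ mg/kg by default,
  monotone PCHIP interpolation in log-log space, strict-monotonicity
  check (a violation signals solver-tolerance trouble), automatic grid
  extension when an inversion target falls outside the mapped range, and
  brentq polishing of inverted doses to 10⁻⁶ relative.
* Michaelis–Menten fits: unweighted least squares on pooled replicate
  points, V₀ = max observed rate, Kₘ₀ = concentration nearest half of
  V₀, positivity bounds.  IC50 fits: unit Hill slope (the assay model has
  none); a free-slope variant exists behind a flag.
* BMD: exponential c·(1−exp(−(d/k)ⁿ)) and Hill c·dⁿ/(kⁿ+dⁿ) families
  with background forced ≈ 0 (predicted curves start at zero
  inhibition), AIC weights, weighted geometric-mean BMD, BMDL = 5th
  percentile of model-averaged BMDs over a residual-resampling bootstrap
  (seeded, reproducible).  This is a deliberately minimal engine, not a
  reimplementation of the full EFSA PROAST suite.
* Sensitivity: one-sided +5% perturbation by default (central optional);
  SC is exactly 1 for a linearly entering parameter and 0 for an inert
  one (tested identities).
* Degenerate inputs raise informative errors: all-zero rates, missing
  compartments/Kp, flow imbalance > 1%, activities without a 10–90%
  transition, flat dose-response curves, BMR outside the fitted range.

## Synthetic data: what it does and does not emulate

Generators reproduce the *statistical shell* of the assays: triplicate
incubation rates with 5% proportional CV on the Michaelis–Menten curve
(1–100 µM, truncated at zero), triplicate activities with 3
percentage-point additive noise on the unit-slope logistic (clipped to
0–120% of control), and noisy cumulative urinary curves forced
non-decreasing.  Every generator is a pure function of (parameters,
seed).  They do not emulate chromatographic calibration, background
hydrolysis corrections, inter-day drift, or any systematic deviation from
the generating model — so recovery tests demonstrate estimator
correctness and pipeline self-consistency, not robustness to real-world
model misspecification.

## Known limitations

* The absolute dose scale of the predicted dose–response curves (and
  hence BMD/BMDL values) is highly sensitive to fup and the estimated
  partition coefficients; with the shipped literature-style defaults the
  package's BMDL₁₀ values sit well above the published point-of-departure
  range for this compound, while the structural behaviour (species
  ordering, monotonicity, mass balance, sensitivity ranking) is
  preserved.  Users with measured fup or Kp values should override the
  defaults.
* The human:rat unbound-Cmax contrast reflects the balance between
  blood-borne hydrolysis (strongly rat-favoured) and flow-limited hepatic
  clearance; with the default inputs the model yields roughly an
  order-of-magnitude contrast at equal oral doses.
* Single acute oral dosing only: no AChE resynthesis/steady-state
  inhibition for repeated exposure, no dermal/inhalation routes, no
  enterohepatic recirculation, no esterase-inhibition feedback on
  clearance, no interindividual variability.
* The BMD engine covers two families with AIC weighting; quantal
  endpoints and covariate submodels are out of scope.

## Problem sizes used in the shipped analyses

Dose grids of 20–40 log-spaced points for Cmax maps, 16-point
concentration grids for predicted curves, 200 bootstrap replicates for
BMDL (100 in some tests), and 20-seed averages for recovery studies; all
chosen as the package's defaults for routine desk analysis and easily
raised via options.
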