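# Methods

## Model

`sweatkin` models steady-state urea transport from a blood capillary to
the skin surface along a single sweat gland, through three compartments.

**Plasma (0-D).** The capillary holds urea at the fixed concentration
`C_blood` (mol m⁻³ ≡ mmol L⁻¹) and exchanges with the ISF at the molar
rate `J = k_DE (C_blood − C̄_ISF) V_p`, where `C̄_ISF` is the spatial mean
of the ISF field (the capillary has no spatial structure, so a mean-field
coupling is the consistent choice). Water filters across the capillary
wall by the Starling relation `Q = L_p,c A_c (P_c − P_ISF)`; a negative
pressure difference gives reverse filtration and is not clamped.

**ISF (1-D).** A convection–diffusion equation with diffusivity `D_ISF`,
advection at `u_ISF = Q / A_ISF`, the plasma flux distributed uniformly
over the ISF volume, and a drain through the gland wall. The domain length
is `V_ISF / A_ISF ≈ 27 µm` — the only length consistent with the tabulated
volume and cross-section. Both ends are closed (zero total flux): the
plasma source and wall drain are distributed, so no boundary throughput is
needed.

**Gland lumen (1-D, length `L` = 4 mm).** Convection–diffusion with sweat
diffusivity `D_sw` and water velocity `u_sg`. Water flow follows a
Poiseuille law `Q_sg = ΔP/R` with `R = 128 μ L/(π d⁴)`; the lumen velocity
is scaled by the measured normalized sweat velocity `u_sweat,n`
(dimensionless, relative to the passive reference velocity
`u_passive = 3×10⁻⁴ m s⁻¹`), so stimulated-sweating collections enter the
model through their measured rate. Urea enters by (i) Fickian wall flux
`D_sg,wall (C̄_ISF − C_sg)/h_sg` per unit wall area, applied over the
lumen perimeter `π d` and distributed along the whole gland, and (ii) the
active-transport rate `S` (mol m⁻³ s⁻¹), representing carrier-mediated
transport by urea transporters in the gland epithelium. The readout is the
concentration at the gland exit — the skin surface, the only collectable
point — after dilution by co-secreted water:
`C_sweat = C_exit / (1 + K_w/u / u_sg,n)`.

### Pressure coupling

Two modes:

* `fixed` (default): the interstitial pressure keeps its tabulated value
  and the gland driving pressure is calibrated so the passive Darcy
  velocity equals `u_passive` (`ΔP = u_passive A_sg R ≈ 1.53 kPa`). Since
  the measured sweat velocity is injected directly via `u_sweat,n`, full
  pressure dynamics add nothing to the readout.
* `balanced`: solves for the interstitial pressure at which Starling
  inflow equals gland Darcy outflow (skin at 0 mmHg) — the feedback by
  which a blocked gland (R → ∞) drives the interstitial pressure up to the
  capillary pressure and shuts down filtration. Provided for studying that
  mechanism; the default mode is used everywhere else.

### Active-transport bookkeeping (`s_mode`)

The natural "transfer" reading — a volumetric sink `S` in the ISF balanced
by a source in the gland — fails quantitatively with the tabulated
constants: the plasma→ISF clearance capacity is
`k_DE V_p C_blood ≈ 2×10⁻¹⁵ mol s⁻¹`, while physiological `S` values
(0.2–0.5 mmol L⁻¹ s⁻¹) imply transfer rates of `10⁻¹⁴–10⁻¹³ mol s⁻¹` —
10–100× more than plasma can resupply. Any steady state with an ISF sink
of that size drives the ISF concentration far below zero. The package
therefore offers three modes:

* `gland_source` (default): `S` sources urea into the gland lumen only,
  drawing on the epidermal/cellular urea reservoir rather than the ISF
  pool. Epidermal urea accumulation is a documented phenomenon in uremia
  and is the only supply consistent with the magnitudes involved.
  Concentrations remain non-negative for every `S ≥ 0`.
* `literal`: the same volumetric rate as sink (ISF) and source (gland).
  The two compartments have different volumes, so this does not conserve
  mass; the implied external gain/loss is reported as
  `active_transfer_imbalance`. Usable only for `S ≲ 0.005`.
* `conservative`: ISF sink `S`, gland source rescaled by
  `V_ISF/(A_sg L)` so the molar transfer balances exactly. Same small-`S`
  restriction.

In every mode the solver verifies the discrete budget — plasma inflow plus
active bookkeeping equals advective outflow — and reports the relative
residual (`< 10⁻¹⁰` in practice; the finite-volume scheme telescopes
exactly). Solutions with negative concentrations beyond round-off raise
rather than being silently clipped.

## Numerics

The steady problem is **linear** in the two concentration fields, so
instead of pseudo-time marching the package assembles the finite-volume
operator (first-order upwind advection, central diffusion) and solves it
directly; the result is the exact steady state of the discrete scheme, in
one ~2 ms dense solve at the default resolution (40 ISF + 200 gland
cells). This matters because the inverse loop and the sensitivity analysis
run thousands of forward evaluations.

Boundary conditions: ISF ends closed; gland inflow is the Danckwerts
flux condition (total inlet flux `u · C_in` with `C_in = 0`: pure water
enters the secretory coil), gland outlet is advective outflow with zero
diffusive flux. The flux-form inflow is deliberate: imposing a Dirichlet
value on the inlet face combines with upwind numerical diffusion
(`u Δy/2 ≫ D_sw` at practical resolutions) to create a spurious inlet
leak, which the stiff ISF balance amplifies into a grid-persistent ~0.5%
readout error; with the flux form the solver matches the closed-form
constant-coefficient solution to ~10⁻¹⁰ (verified in the test suite
against an independently derived analytic oracle: uniform ISF profile plus
exponential gland profile when ISF advection is switched off).

Grid defaults were chosen so that halving the mesh changes the readout by
well under 0.5%; the gland exit value is insensitive to the cell Péclet
number because the steady balance there is advection + wall exchange +
source, not diffusion.

## Inverse estimation

One measured sweat value per sample; the estimator alternates:

1. **Loop 1 (blood refinement).** The forward map is strictly increasing
   in `C_blood`, so the squared-error minimum on the search bracket
   (0–60 mmol/L, covering the clinical range with margin) is found by a
   bracketed root solve to relative tolerance 10⁻⁶. Measured values below
   or above the attainable range return the bracket edge with a warning
   flag.
2. **Loop 2 (parameter refinement).** Bounded coordinate descent over the
   free parameters — by default the three the readout is most sensitive to
   (`S`, `D_sw`, `K_w/u`) — on the squared sweat error plus a quadratic
   prior `λ Σ ((θ − θ_ref)/θ_ref)²` (λ = 1 by default; the `S` prior uses
   an absolute scale of 1 mmol L⁻¹ s⁻¹ since its reference can be 0).
   Coordinate moves are accepted only if they lower the objective, and a
   parameter update whose subsequent loop-1 refit does not lower the
   squared error is rejected (the outer loop then stalls), so the recorded
   error trace is non-increasing by construction.

Iteration stops when the squared error drops below 0.01 mmol² L⁻², on
stall, or at the outer-iteration cap (20); non-convergence returns the
best estimate so far, flagged, never an exception.

**Priors for `S`.** No literature value exists for the active-transport
rate; the estimator centers its prior on published per-timepoint medians
from dialysis patients — 0.51 mmol L⁻¹ s⁻¹ before and 0.21 after a
session, 0.36 (the midpoint) when the timepoint is unknown — and, in full
mode, starts loop 1 with `S` at that center. With a regularized loop 2
this makes the procedure's fixed point prior-consistent and exactly
independent of the blood-urea initialization (verified across
initializations 0–50 mmol/L). The passive comparator mode pins `S = 0`
throughout and frees the remaining parameters.

**Identifiability.** A single scalar observation cannot jointly determine
`C_blood` and `S`: the model is affine in both, and along the exact-fit
ridge `∂C_blood/∂S = A_sg L/(k_DE V_p) ≈ 217` mmol/L per mmol L⁻¹ s⁻¹,
independent of sweat rate. Any uncertainty in a patient's true `S`
therefore maps into blood-estimate error with a gain of ~217: an `S`
spread of 0.08 mmol L⁻¹ s⁻¹ (the pre-dialysis population spread used by
the cohort generator) implies an irreducible blood error of
~17 mmol/L. This is the dominant error in the end-to-end synthetic
validation and is a property of the physics (weak passive transmission),
not of the optimizer. Accurate single-sample estimation requires either a
per-patient `S` calibration (e.g. one paired blood–sweat measurement) or a
much stronger passive pathway than the tabulated constants allow.

## Sensitivity analysis

`parameter_cv` perturbs one parameter (or the plasma input `Cp`) with 100
Gaussian draws, SD = 10% of the baseline, truncated positive by redraw
(negligible at 10% SD; relevant for exploratory large-SD runs), and
reports CV = SD/mean of the simulated sweat concentration. The operating
point — `Cp = 6.4` mmol/L (mean post-dialysis blood urea), `S = 0.36`
(midpoint of the per-timepoint medians), `u_sweat,n = 2.8` (a
stimulated-collection rate; at this value the dilution elasticity
`K_w/u/(u_sg,n + K_w/u)` is ≈ 0.47, matching the observed dilution-ratio
CV) — is configurable and documented in `OperatingPoint`.

At this operating point the model's CV ordering is: `S` (~8%) >
`K_w/u` (~4%) > `Cp` (~0.7%) > `h_sg` ≈ `D_sw` ≈ 0. The near-zero wall and
diffusivity sensitivities follow from the physics: wall exchange is ~60×
faster than advective washout, so it saturates (its rate constants cancel
from the steady state), and the gland Péclet number `u L/D_sw ≈ 10³`
makes axial diffusion irrelevant to the exit concentration.

`initialization_robustness` re-runs the full estimator across a sweep of
blood-urea initializations and reports the CV of the resulting RMSPE; for
this estimator the result is 0 up to solver tolerance, by the design of
loop 1.

## Synthetic cohorts

`generate_cohort` emulates the structure of a paired pre/post dialysis
study: per patient a lognormal pre-dialysis blood urea (median
20 mmol/L, log-SD 0.35), a Beta-distributed urea reduction ratio (mean
0.7), giving a post-dialysis cohort mean of ≈ 6.4 mmol/L; truncated-normal
active-transport rates per timepoint (means 0.51/0.21, SDs from the
reported IQRs via IQR/1.35); uniform GFR (2–12 mL/min/1.73 m²) and
normalized sweat velocity (1–4); sweat produced by the forward model plus
5% multiplicative noise; and 20% of patients with missing sweat values
(emulating insufficient collection volume). All distribution families are
generator choices — only their location anchors are empirical — and every
one is a config field. Output is byte-identical for a fixed seed.

What the generator does **not** emulate: intra-dialytic urea rebound,
assay-specific error structure, circadian variation, or any correlation
between `S` and uremic severity. Passing tests on these cohorts
demonstrate the pipeline's internal consistency (the estimator inverts the
same physics that generated the data), not clinical accuracy on real
patients.

## Problem sizes

The test suite and the acceptance script use 100 Monte-Carlo draws per
sensitivity target (the analysis's defined sample size), cohorts of 10–32
patients, and grids of 16×64 (tests) or 40×200 (default) cells; these
sizes put every analysis in the seconds range while keeping discretization
error well below the assertion tolerances.

## Known limitations

* With the tabulated constants, passive transmission from blood to sweat
  is at most a few percent, so simulated sweat urea is always **below**
  blood urea at physiological `S`; observed sweat-above-blood ratios
  require either a larger active rate than the per-timepoint medians or a
  transport pathway the parameter set does not support (see the supply
  analysis above). Consequently the model family cannot reproduce reported
  sweat-vs-blood scatter with sweat > blood at those `S` values.
* The sweat diffusivity `D_sw` has essentially no influence on the steady
  readout (Péclet ≈ 10³); analyses that attribute large output variance to
  it are incompatible with this steady-state formulation.
* Single-sample blood estimation carries the ~217× identifiability gain on
  `S` uncertainty described above; reported RMSPEs on synthetic cohorts
  (~100%) are the honest consequence.
* Steady state only: no transient sweat readouts, no 2-D/3-D gland
  geometry, no uncertainty quantification on estimates.
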