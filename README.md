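# sweatkin

Kinetic modelling of urea transport from blood to sweat, and inverse
estimation of blood urea concentration from sweat measurements — aimed at
non-invasive monitoring of hemodialysis (HD) adequacy in end-stage renal
disease, where treatment quality is judged by how well blood urea is
cleared but assessing it normally requires repeated venipuncture.

## The model

Urea travels from a blood capillary through the interstitial fluid (ISF)
into the sweat-gland lumen and out to the skin surface:

* **plasma → ISF**: urea flux `J = k_DE · (C_p − C_ISF) · V_p` and Starling
  water filtration `Q = L_p,c · A_c · (P_c − P_ISF)`;
* **ISF**: 1-D convection–diffusion with the plasma flux as a distributed
  source and Fickian exchange across the gland wall
  (`D_sg,wall · ΔC / h_sg` per unit wall area);
* **gland lumen**: 1-D convection–diffusion toward the skin, water flow by
  a Poiseuille law `Q_sg = ΔP / R`, `R = 128 μ L / (π d⁴)`, scaled by the
  measured normalized sweat velocity; an active-transport rate `S`
  (mol m⁻³ s⁻¹, mediated by urea transporters) sources urea into the
  lumen; the exiting concentration is diluted by co-transported water,
  `C_sweat = C_exit / (1 + K_w/u / u_sg,n)`.

The steady state is linear in the concentrations and is solved exactly by
a finite-volume direct solve (upwind advection, Danckwerts inflow); the
discrete urea budget closes to round-off and is reported per run.

The **inverse problem** — given one measured sweat urea value, find the
blood value — is solved by a double-loop scheme: loop 1 refines blood urea
(the forward map is strictly monotone, so this is a bracketed root solve);
loop 2 refines a small set of transport parameters (`S`, `D_sw`, `K_w/u`)
by bounded coordinate descent on the squared sweat error plus a quadratic
prior, stopping when the squared error drops below 0.01 mmol² L⁻².
A passive comparator mode pins `S = 0`.

Supporting modules provide method-comparison statistics (RMSE, RMSPE,
Pearson/Spearman with Fisher-z CIs, Bland–Altman, Wilcoxon signed-rank,
GFR stratification), Gaussian-perturbation sensitivity analysis, and a
seed-deterministic synthetic HD cohort generator (paired pre/post samples,
sweat produced by the forward model itself).

## Worked example

```python
from sweatkin import EstimationConfig, default_parameters, estimate_blood_urea, simulate

params = default_parameters()
truth = params.replace(S=0.36, u_sweat_n=2.0)   # active transport, stimulated sweating
measured = simulate(20.0, truth).C_sweat        # 1.302 mmol/L of sweat urea
full = estimate_blood_urea(measured, params.replace(u_sweat_n=2.0), EstimationConfig())
passive = estimate_blood_urea(measured, params.replace(u_sweat_n=2.0),
                              EstimationConfig(), mode="passive")
print(full.C_blood_final, passive.C_blood_final)
```

prints `20.00 60.00`: the full model recovers the true blood urea
(20 mmol/L) from a sweat value of 1.302 mmol/L, while the passive
comparator — forced to explain the sweat signal by diffusion and dilution
alone — runs into its 60 mmol/L search bound, the characteristic
overestimation of passive-only inversion. `examples/` contains this and
three more narrated scripts (forward simulation, sensitivity table,
full synthetic-cohort validation); each prints the numbers it computes and
one line on what they mean.

A command-line interface mirrors the library:

```sh
sweatkin synth --seed 7 --out cohort.csv --truth truth.csv
sweatkin estimate --input cohort.csv --out estimates.csv
sweatkin evaluate --estimates estimates.csv --out report.json
sweatkin sensitivity --seed 42 --out cv_table.csv
```

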