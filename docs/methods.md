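# Methods

`flowamide` is a desk-scale re-implementation of an autonomous two-stage
Bayesian-optimisation campaign for the direct enzymatic synthesis of
*N*-benzyl acetoacetamide (the β-ketoamide **3**) from a β-ketoester and
benzylamine over immobilised *Candida antarctica* lipase B (Novozym 435) in a
packed-bed flow reactor. The physical rig — pumps, packed bed, on-line uHPLC —
is replaced by a calibrated reaction simulator; every algorithmic component
(design generation, GP surrogates, multiobjective Thompson sampling, Pareto
scalarisation, mixed-variable BO, model interpretation) is implemented in the
package and exercised against that simulator.

## Design space

Four continuous reactor variables with box bounds — ester concentration
200–350 mM, amine equivalents 1–4, residence time 1–10 min, temperature
25–60 °C — plus a categorical solvent with levels MeCN, 2-MeTHF, anisole and
dioxane. All GP and acquisition computation is done on the unit cube; physical
units are used at the simulator interface and in all reports. Initial designs
are seeded random Latin hypercubes (uniform within bins; the sampling dialect
is not prescribed by the source study, so the plain `scipy.stats.qmc` LHC is
used). The solvent-stratified variant assigns levels to LHC rows by a seeded
block permutation: the continuous part of each per-solvent subset is balanced
but not itself an LHC.

## Reaction simulator (synthetic-data generator)

The two observables are normalised uHPLC peak areas of product **3** and
enamine impurity **4**, identified with fractional yields (unit response
factors). The noiseless surface is

* product: `A_s · u_τ,s(τ) · u_C,s(C) · u_T,s(T) · u_eq(eq)`, clipped so that
  product + impurity ≤ 1 (mass balance on the ester);
* impurity: `b_s + m·(eq − 1)`, independent of time, concentration and
  temperature (nucleophilic addition with a bimolecular rate-determining
  step).

The solvents fall into two shape families. The ethers (dioxane, 2-MeTHF) have
an interior residence-time optimum `u_τ = (τ/τ*)·exp(1 − τ/τ*)` and a Gaussian
concentration optimum; the nitrile/aromatic pair (MeCN, anisole) saturates
sigmoidally in time and decays linearly in concentration. Temperature enters
through a Gaussian optimum everywhere, and equivalents give the product only a
small saturating boost `1 + δ(1 − e^{1−eq})`, δ ≤ 0.05. Observation noise is
iid Gaussian (σ = 0.01 by default) on both channels, truncated to [0, 1] and
re-clipped; an optional first-order catalyst-deactivation factor
`exp(−κ·t)` (default κ = 0, since the stability study found none) uses the
campaign clock.

**Calibration.** Four anchors pin the surface: (A1) 94% yield at 209 mM,
1.7 equiv, 8.4 min, 30 °C in 2-MeTHF; (A2) 56% yield at 240 mM, 1 equiv,
8.71 min, 46 °C in MeCN; (A3) full conversion with selectivity
(product/impurity) 5.76 at the dioxane conversion-argmax over a fixed
17×7×19×8 grid; (A4) selectivity 16.0 at 90% conversion at the MeCN
constrained ratio-argmax over the same grid. A3/A4 translate in closed form to
impurity values 1/6.76 (at 4 equiv, dioxane) and 0.9/17 (at 1 equiv, MeCN).
The fit is decomposed: amplitudes are profiled out analytically (the product
surface is linear in `A_s`), impurity intercepts come from the closed forms,
and the remaining shape parameters are fitted by seeded multi-restart
Nelder–Mead under box bounds (τ* ∈ [4, 7] min, C* ∈ [260, 300] mM, so that the
"optimum near 5 min / near 280 mM" behaviour emerges from calibration rather
than being hard-coded). Residual tolerances are ±0.005 on yield fractions and
±0.1 on selectivity ratios; infeasibility raises an error reporting the worst
residual.

Two consequences of the anchors are worth recording. First, the shared
impurity slope `m` is not printed anywhere; it defaults to `(i_A3 − i_A4)/3 ≈
0.0317` per equivalent, the unique value that makes the two *anchored*
intercepts (MeCN, dioxane) coincide — the source study states the impurity law
is solvent-independent, so calibration minimises solvent dependence subject to
the anchors. Second, mass balance at A1 caps the 2-MeTHF intercept at
`1 − 0.935 − 0.7m ≈ 0.043` (evaluated at the anchor's tolerance edge), 0.010
below the MeCN/dioxane value of 0.0529. This residual offset is structural:
no parameter choice satisfying A1 and A4 can remove it. It is about one third
of the impurity signal's standard deviation over the design space and is
therefore resolvable by a well-fitted model; see *Known limitations*.

The stage-1 narrative claims of the source (64% conversion at selectivity
30.4; front mapped after 41 experiments) are deliberately **not** anchors:
they are inconsistent with A4 under a single equivalents-only impurity law.

**Stability protocol.** The most forcing corner of the space (350 mM, 4 equiv,
10 min, 60 °C) is run for 3 h per solvent, cycling through all four solvents
twice over 24 h (two samples per hour by default). With κ = 0 the per-solvent
round means agree within the noise tolerance; with κ > 0 round 2 falls below
round 1 in every solvent.

## Gaussian-process surrogates

Targets are standardised; the kernel is signal variance × Matérn-5/2 ARD over
the continuous unit-cube dimensions × a unit-lengthscale squared-exponential
over two latent solvent coordinates. Latent coordinates are learned jointly
with the hyperparameters by maximising the log marginal likelihood
(multi-restart L-BFGS-B; 10 restarts for standalone fits, 3 inside BO loops).
Identifiability: the first solvent is pinned to the latent origin and the
second to the first latent axis, so a 1D collapse of the embedding is an
outcome, not an assumption. Two regularisers stabilise the n ≈ 39 fits:

* a zero-mean Gaussian prior with σ = 1.5 on the free latent coordinates
  (MAP estimation) — without it, individual noise draws occasionally favour a
  solution that separates all solvents widely and absorbs noise into
  per-solvent interpolation;
* an optional noise floor: the fitted noise standard deviation may not drop
  below a stated fraction of the known instrument noise (campaign fits use
  half of σ = 0.01).

Hyperparameter bounds: lengthscales in [0.01, 100] on the unit cube, latent
coordinates in [−5, 5]. Cholesky jitter is 1e-10 × signal variance. Posterior
prediction de-standardises mean and variance; leave-one-out cross-validation
uses the closed-form LOO identities at the full-fit hyperparameters (a
rank-one downdate, not a refit), reporting R² = 1 − Σ(y−ŷ₋ᵢ)²/Σ(y−ȳ)².
Degenerate (zero-variance) targets yield a flat fit with lengthscales at
their upper bound and a warning; LOOCV refuses them.

## Stage 1 — multiobjective BO (TSEMO-style)

Objectives (−product, +impurity) are minimised over the continuous variables
with solvent fixed (MeCN). Each iteration: fit one GP per objective; draw one
approximate posterior sample per objective through a 500-feature spectral
expansion (Matérn-5/2 frequencies are multivariate-t with five degrees of
freedom; conditioning the Bayesian linear model on the data gives a
deterministic, cheaply evaluable draw per seed); solve the sampled
two-objective problem with an in-package NSGA-II (population 100 ×
100 generations by default, SBX crossover η = 15, polynomial mutation η = 20);
propose the inner Pareto point with the largest hypervolume improvement over
the observed front, with the reference point at the observed nadir plus a 10%
span margin. The study budget is a 9-point LHC (the 2n + 1 rule with n = 4)
plus 60 sequential proposals, 69 experiments in total, with no automated
stopping rule. An inner-solver failure falls back to a random in-bounds
candidate with a warning.

## Pareto analysis and weight inference

The observed front is the nondominated subset (maximise product, minimise
impurity), ordered by increasing product. The preferred trade-off is found by
the diminishing-returns walk: starting from the lowest-product end, a step to
the next front point is accepted while the percentage product gain is at
least the percentage impurity increase (ties accept; a zero-impurity step
falls back to absolute changes with a warning). Scalarisation weights are
then reverse-engineered by an LP that maximises the margin ε subject to
`f(preferred) + ε ≤ f(j)` for all other front points, with both weights
active (|w_amide| ≥ 0.05, w_enamine ≥ 0.05) and the ℓ1 normalisation
|w_amide| + w_enamine = 1. The published pair (−0.2667, 0.773) sums to 1.04,
so the source's normalisation differs or reflects rounding; all downstream
behaviour is invariant to positive rescaling, and the published pair is kept
available as `PAPER_WEIGHTS`. If the preferred point lies on a non-convex
stretch (margin below the 1e-6 floor) `infer_weights` raises; the full-study
orchestrator alone retries at the nearest front point by product distance,
with a warning, so a noisy campaign still completes.

## Stage 2 — scalarised mixed-variable BO (ALaBO-style)

A single latent-variable GP is fitted to f = w_amide·product +
w_enamine·impurity, recomputed from the stored raw observations (so weights
can change without rerunning experiments). The acquisition is expected
improvement for minimisation, maximised separately for each solvent over the
continuous unit cube by 20-start L-BFGS-B (19 seeded random starts plus the
incumbent); the best (solvent, continuous) pair is proposed, which guarantees
feasible categorical proposals. The source names ALaBO but not its
acquisition or its "adaptive" element; EI with a fixed kernel is used and
recorded as a deliberate simplification. Budget: a 12-point solvent-stratified
LHC (three per solvent) plus 27 proposals, 39 experiments.

## Interpretation

Variable influence is read from the ARD lengthscales (smaller = more
influential), reported with log10 values for plotting. Solvent relationships
are read from the latent embedding (coordinates, pairwise distances, and a
1D-collapse flag when the second-axis coordinate range is below 1e-3 of the
first). Partial-dependence curves sweep one variable over its bounds with the
others held at the fitted campaign's medians (the stage-2 campaign, since
those are the models being interrogated), one curve per solvent, 50 grid
points by default. `campaign_report` writes all tables (Pareto front with
percentage changes, lengthscales, latent coordinates, PDPs, best conditions
per solvent, conversion/selectivity summaries, the space-time yield of the
best point) as CSV/JSON with fixed float formatting, so reruns are
byte-identical.

Space-time yield is `STY = c · y · M / t` in g L⁻¹ h⁻¹, with the residence
time converted to hours and the product molar mass fixed at 191.23 g/mol
(C₁₁H₁₃NO₂). Back-computing the study's flow-optimum entry with this standard
formula gives ≈268 g L⁻¹ h⁻¹ against a printed 274, a discrepancy that
presumably reflects reactor void-volume accounting; the batch literature
entry (1.18 g L⁻¹ h⁻¹) is reproduced exactly and is the arithmetic check
used in the tests.

## Orchestration and reproducibility

`run_full_study` chains calibrate → stability → stage 1 → Pareto/weights →
stage 2 → interpretation; a single global seed fans out to per-stage seeds by
fixed offsets, and every campaign CSV (versioned header, 10-significant-digit
floats), weights file and report is reproducible byte-for-byte from
(config, seed). The campaign clock charges each experiment its residence time
plus a 10-minute overhead, which puts the default 108-experiment study at
roughly 29 simulated hours. A YAML configuration carries the design space,
simulator settings, budgets and all solver constants; a thin `flowamide` CLI
exposes each stage as a subcommand.

## What the simulator does and does not emulate

It reproduces: the printed anchor performances, the solvent shape families
and their consequences (interior time/concentration optima for the ethers,
monotone behaviour for MeCN/anisole), the solvent-independent linear impurity
law, observation noise of the on-line uHPLC, and (optionally) slow catalyst
decay. It does not model transport or enzyme kinetics (no kcat/KM, no
pressure or flow-rate effects), response-factor differences between
normalised areas and concentrations, or the stage-1 point cloud of the real
campaign — the raw experimental data are not packaged, so tests validate
behaviourally (oracle hypervolume fractions, solvent identification,
lengthscale orderings) rather than against experimental scatter.

## Test problem sizes and stochastic policy

Stochastic behavioural checks run as seeded replicate suites: 10 stage-2
campaigns at σ = 0.01 (shared between the solvent-identification and
interpretation tests), 10 noiseless stage-2 campaigns for oracle recovery
(pass bar 8/10), one full 69-experiment noiseless stage-1 campaign against a
40×13×37×15 grid-oracle front (≥ 95% of oracle hypervolume), and ≥ 7/10 bars
on the interpretation suite. BO-loop GP fits use 3 restarts and the unit
suite uses reduced NSGA-II budgets (population 80 × 60 generations in the
oracle test); these sizes are the package's chosen defaults for a single-CPU
run and are recorded in the test configuration objects.

## Known limitations

* **Impurity latent spread.** Because the anchors force the 2-MeTHF impurity
  intercept 0.010 below the other solvents (see *Calibration*), the impurity
  embedding resolves a genuine separation of ~0.1–0.4 latent units against
  product spreads of ~1–2.5. The interpretation check asking the impurity
  latent spread to stay below 0.1× the product's therefore fails in a
  substantial fraction of seeds: the embedding is correctly detecting a real,
  anchor-mandated effect, not overfitting. The qualitative claim — the
  impurity embedding is far tighter than the product's and flags a 1D
  collapse — holds in every replicate.
* The LP normalisation of inferred weights is a package convention; only the
  argmin property of the published weight pair is reproducible.
* The NSGA-II and spectral-sampling components are compact re-implementations
  adequate for 4–6 dimensional, two-objective inner problems; they are not
  general-purpose solvers.
* With MeCN's impurity almost flat in everything but equivalents, the true
  stage-1 front is thin; under noise the observed front partly reflects noise
  realisations, and the inferred weights are accordingly more
  impurity-weighted than the published pair.
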