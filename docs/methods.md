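# Methods

`lvmech` models the mechanics of the left ventricle (LV) at two cardiac
phases — end-diastole and end-systole — estimates subject-specific
contractility from volume and strain "measurements", and asks whether the
resulting biomechanical features separate healthy ventricles from those
with a recent myocardial infarction (MI). This note records the model, its
assumptions, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Passive myocardium

The passive response is the invariant-based Holzapfel–Ogden law

```
Psi = a/(2b) [exp(b(I1bar − 3)) − 1]
    + Σ_{i∈{f,s}} a_i/(2b_i) [exp(b_i(I4i − 1)²) − 1]      (only if I4i > 1)
    + a_fs/(2b_fs) [exp(b_fs I8²) − 1]
```

with fibre and sheet directions `f0`, `s0`, squared stretches
`I4f = f0·C f0`, `I4s = s0·C s0`, coupling `I8 = f0·C s0`, and
`I1bar = J^(−2/3) tr C`. Fibres and sheets bear load only when taut, so
the anisotropic terms switch off under compression. Default coefficients
are the cohort-average values for healthy controls and for remote
myocardium of MI subjects (`data/healthy.yaml`, `data/mi_remote.yaml`;
`a`-type in kPa, `b`-type dimensionless).

Two deliberate choices:

* The **isotropic term uses the isochoric invariant** `I1bar`. With the
  unsplit `I1` the reference configuration carries a spurious hydrostatic
  stress `a·I`; the isochoric split makes the reference state exactly
  stress-free while leaving every isochoric response identical (the solver
  works at `J ≡ 1`).
* **Scar stiffening** scales the whole elastic energy by `1 + 49·M`, where
  the infarct extent `M ∈ [0,1]` is 1 in the scar, 0 in remote muscle, and
  decays linearly over a 10 mm transition band. Fully infarcted tissue is
  therefore exactly 50-fold stiffer at any deformation. The volumetric
  penalty `beta_s (ln J)²` (`beta_s = 100 kPa`) is an incompressibility
  device, not tissue, and is not scaled.

The Cauchy stress is the analytic push-forward `σ = J⁻¹ (∂Psi/∂F) Fᵀ`
plus the penalty term `(beta_s/J) ln(J²) I`; a finite-difference oracle
checks the derivative at random deformations to 1e-4 relative.

## Active tension and myofilament kinetics

Active stress is rank-one along the current fibre direction,
`σ_a = T_a f̂⊗f̂`, with

```
T_a = T_req · C(λ_f, z) · (1 − M)
```

`T_req` (kPa) is the tension generated at unit fibre stretch — the
contractility parameter estimated per subject; scar does not contract.
`C` collects the myofilament kinetics in a fading-memory crossbridge
form: `C = z · g(λ) · h(Q)` with length dependence
`g = max(0, 1 + β₀(λ−1))`, a force–velocity factor `h(Q)` with curvature
`α` driven by three fading-memory variables `dQ_i/dt = A_i dλ/dt − α_i Q_i`,
and binding-site availability
`dz/dt = r_on·ca(t)·(z_max(λ) − z) − r_off·z` driven by a prescribed,
spatially homogeneous calcium transient `ca(t) = (t/τ) e^(1−t/τ)`
(contraction triggered simultaneously everywhere). Normalization is fixed
by `C = 1` at `λ = 1`, full activation, no stretch-rate history — making
`T_req` literally the tension at unit stretch. `C` at the configured
end-systolic time (325 ms) is the biomarker `C^s`.

All rate constants live in `data/active_default.yaml`. They are inputs:
`β₀ = 4.9` (tension extinguishes near λ ≈ 0.80, the classic steep
ascending limb), binding rates chosen once so that a healthy default run
gives `C^s ≈ 0.3–0.45`, inside the range reported for functional
myocardium. Integration is explicit fixed-step RK4 (0.5 ms, self-
convergence tested at 10× finer steps). Electrophysiological propagation,
regionally varying calcium, and partial contractility inside the scar are
out of scope.

## Geometry, fibres, infarct

The LV wall is a truncated prolate ellipsoid: endocardial equatorial
radius 18.6 mm, long semi-axis 62 mm, wall 8.6 mm (5.2 mm at the apex),
base plane 18.6 mm above the equator. These defaults were chosen once so
the healthy forward model reproduces a cohort-typical end-diastolic
volume (≈127 ml at 8 mmHg filling pressure from an unloaded cavity of
64.5 ml); per-subject size is set by isotropic scaling to a target EDV.
Quadrature excludes a small cap at the apex pole (coordinate
singularity); cavity volumes are closed-form.

Fibre and sheet orientations follow the rule-based construction: helix
angle linear through the wall from −60° (endo) to +60° (epi), sheet angle
−45° to +45°, orthonormal by construction.

Strain bookkeeping uses 24 regions — four short-axis slices from the base
toward mid-ventricle × six sectors (AHA convention). Segmental
circumferential strain is the engineering stretch of the mid-wall
circumferential direction, averaged per region; systolic strains are
referred to end-diastole (the convention of CMR strain reporting),
diastolic strains to the unloaded state. Shortening is negative.

The infarct is a single contiguous transmural region: circumferential
half-angle 1.2 rad about π/4, core below 2 mm above the equator, 10 mm
linear transition band, giving ≈39 % of wall volume and 13 remote
segments of 24 — the cohort-mean scar. Regions are classified
remote/transition/infarct from mean mid-wall M (thresholds 0.05/0.5).

## Reduced-order equilibrium solver

The imaging-scale fluid–structure model is replaced by a quasi-static
energy-minimization stand-in whose kinematic ansatz is exactly
incompressible. In reference cylindrical coordinates,

```
z = λ_z Z,   φ = Θ + τ(Z),   r = sqrt(R²/λ_z + s(Z,Θ))
```

The deformation gradient of this map is triangular with `det F ≡ 1`
pointwise — incompressibility is built in, not penalty-enforced
(`max|J−1|` is machine precision at every quadrature point). Degrees of
freedom: global axial stretch, three longitudinal inflation knots (zero
at the apex), linear base-to-apex twist (bounded to ±0.6 rad), and one
infarct-localized bulge mode that lets the non-contracting scar stretch
while remote muscle shortens. Equilibrium minimizes

```
Π = ∫ [(1 + 49M) Psi + W_act] dV − P·V_cav
```

(L-BFGS-B on scaled dofs; cavity volume is analytic in the dofs).

**Coupling kinetics and equilibrium.** During systole each point's fibre
stretch is assumed to ramp linearly from its end-diastolic value to its
end-systolic value over the systolic interval, so `C` at end-systole is a
pointwise function of the end-systolic stretch. The active stress then
derives from an exact potential `W_act = T_req(1−M)·G(λ_f)` with
`G(λ) = ∫ C(ℓ)/ℓ dℓ` (whose Cauchy stress is exactly `T_a f̂⊗f̂`), which
we tabulate on a (λ_ED × λ_ES) grid and interpolate. Systolic equilibrium
is therefore a single deterministic minimization. A naive alternation
between tension update and equilibrium solve was tried first and
oscillates between a contracted and an inflated branch (the
tension–volume feedback is non-contractive); the potential formulation
removes the problem and is ~10× faster.

**Known scale gap.** At the published contractility scale
(T_req ≈ 157 kPa) the reduced model ejects more than the imaging-scale
model (EF ≈ 0.73 vs ≈ 0.57): a thick-ellipsoid energy balance demands
less tension at matched volumes than the full model. All estimation
experiments are therefore *self-consistency* tests — measurements are
generated by this forward model and the inverse stage must recover the
generating value — which is also the only attainable design given that
the study's subject data are not public. Passing tests show the
estimation machinery is unbiased and precise for this model class; they
do not certify absolute agreement with high-fidelity simulations or
patients.

Resolution: 4 transmural layers × 14 longitudinal × 18 circumferential
quadrature points (1008). Doubling all three changes EDV and ESV by
< 1 % (tested).

## Inverse estimation

The mismatch objective is a weighted least-squares sum over the 24
segmental strains and the cavity volume, normalized by 0.05 (strain) and
10 ml (volume) so both are O(1) at typical error; for MI subjects only
remote segments enter the strain sum (scar properties are prescribed, not
fitted). Diastolic data (EDV + diastolic strains) drive the passive fit;
systolic data (ESV + systolic strains) drive the contractility fit.

* `fit_passive`: (1) a global stiffness scale on all eight coefficients
  matched to EDV; (2) a fibre-pair (a_f, b_f) scale matched to diastolic
  strains; (3) a joint Nelder–Mead polish. The eight coefficients are
  individually non-identifiable from volume+strain data; the recoverable
  quantity (tested) is the fibre-direction stress response.
* `fit_contractility`: bounded golden-section/parabolic minimization of
  the systolic objective over T_req ∈ [0, 400] kPa, tolerance 0.1 kPa.
  Every trial starts the equilibrium search from the end-diastolic dofs so
  the objective is a path-independent function of T_req (warm-starting
  across trials costs ~1 kPa of reproducibility; measured). Noise-free
  recovery error is ≈ 0.3 kPa; with 1 % observation noise the median
  error over randomized subjects is well under 5 kPa.

All optimizers are deterministic and seed-free.

## Synthetic cohort generator

The study population the pipeline emulates (27 healthy, 11 MI, with
CMR-derived volumes, strains and pressures) is not publicly deposited, so
the generator stands in for it at two fidelities:

* **Calibrated mode** draws feature vectors (T_req, T_a, SBP, EDV, C^s,
  T_a^norm, σ_f, σ_f^norm) from group-conditional truncated multivariate
  normals whose means/SDs are the published group statistics
  (`data/cohort_default.yaml`), e.g. T_req 157±25 vs 156±27 kPa, T_a^norm
  0.45±0.06 vs 0.55±0.07 kPa/mmHg, C^s 0.42±0.04 vs 0.44±0.13. T_a and
  σ_f means are derived from the printed normalized values × group SBP;
  their SDs, and the whole within-group correlation matrix, are
  *assumptions* of this generator (the study's correlation tables are not
  published) and are user-overridable. Notable: corr(T_req, C^s) must be
  ≤ −0.11 for the published outcome correlations to be jointly feasible;
  the default is −0.4. Truncation: ±4 SD and physical bounds, by
  rejection.
* **Pipeline mode** samples ground-truth contractility, pressures and a
  target EDV per subject, runs the forward model, and reports its volumes
  and strains (with optional relative observation noise) as the
  measurement block — the input the inverse stage consumes. Healthy
  subjects load at EDP 8 mmHg, MI subjects at 16 mmHg (population-based
  assumption); MI subjects carry the default scar.

Six-month surrogate outcomes: ΔLVEF at six months is a linear combination
of standardized baseline T_req (negative) and C^s (positive) plus
Gaussian noise, loadings solved so the population correlations equal
−0.79 and 0.70; follow-up GLS correlates 0.73 with baseline GLS.
Infeasible correlation triples raise a config error naming the entries.

What passing calibrated-mode tests shows: the downstream statistics are
computed correctly for data with exactly the published group structure.
What it does not show: that real CMR-derived features have the assumed
correlations, Gaussian shapes, or noise spectra — imaging artefacts,
registration error and population heterogeneity are all absent.

## Classification study

Eight methods: univariate logistic regression (one model per feature),
multivariate logistic regression, KNN (k ∈ {1,3,5,7}), LDA, lasso
logistic regression (L1 penalty grid 0.01–100), boosted entropy-split
depth-2 trees (10 rounds; a stand-in for the proprietary C5.0 family,
with split-usage importance), random forests (50 trees), and a Gaussian
process classifier with one squared-exponential length scale per feature
(GP-ARD). Positive = MI.

Evaluation is nested leave-one-out: an outer LOO for unbiased error, and
for grid-tuned methods an inner LOO *within each outer training set* for
hyperparameter selection (ties take the first grid value); the GP instead
maximizes training marginal likelihood, and the fixed-size ensembles use
single-point grids. Held-out probabilities are thresholded at 0.5.
Features are standardized with training-fold statistics for LR, lasso,
KNN and GP; trees and forests see raw features. The streamlined KNN and
lasso inner loops are regression-tested against the generic grid search.
A mutation test verifies the held-out subject's label cannot influence
its own prediction.

The ensemble is summarized by the upper convex hull of
(1−specificity, sensitivity) points (anchors (0,0), (1,1)) and its
trapezoidal area (AUROC); method ranking is by summed misclassification
error over the three feature panels D1 (full), D2 (no ratios), D3 (ratios
for SBP/T_req). Importance scores — lasso |mean LOO coefficient|, GP-ARD
inverse normalized length scales, boosted-tree split usage, forest
exclusion accuracy drop — are fused by ranking each method's features
0..p−1 and summing. On default calibrated cohorts the two ratio
biomarkers C^s and T_a^norm attain the top mean cumulative ranks (C^s
mostly through the nonlinear methods, which exploit its three-fold larger
MI-group spread), and the D1 hull AUROC averages ≈ 0.85, above D2.

## Association analysis

Pearson correlation with Fisher-z 95 % intervals and two-sided p-values
(`atanh r ~ N(·, 1/(n−3))`); group comparisons use pooled-variance
Student's t (Welch by flag). Significance at 0.05; no multiple-testing
adjustment (matching the emulated analysis); interval coverage is
verified by simulation.

## Problem sizes and determinism

Default runs: calibrated cohorts of 38; large-sample calibration checks
at n = 10⁴–10⁵; ensemble hull AUROC averaged over 30 seeded replicates in
the acceptance script (the replicate SD is ≈ 0.05, so the mean has
standard error ≈ 0.01); noisy-recovery property at 8 randomized subjects.
Every stochastic step takes a seed; identical configuration + seed
reproduces cohort CSVs and `summary.json` byte-for-byte. Solver runs are
seed-free and deterministic.

## Limitations

Single chamber, two time points, no blood flow, valves, atria, inertia or
pericardium; prescribed homogeneous calcium; scar fully stiff and fully
non-contractile (no border-zone viability gradient); the reduced solver's
absolute tension scale differs from imaging-scale models (see above);
segmental strains come from the model's own mid-wall arc definition, not
from image registration; the generator's correlation structure is an
assumption. Conclusions from this package are about the *pipeline* —
estimation fidelity, classifier behaviour, statistical wiring — not about
patients.
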