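# Methods

## Model

For a square K×K mobility table (default K = 3: low/medium/high education)
with origin i, destination j, the logistic diagonal reference model is

    logit P(Y_ij = 1 | x) = w·γ_i + (1 − w)·γ_j + δ_d·1[down] + δ_u·1[up] + x'β

- γ_k = log μ_kk: diagonal intercepts, the baseline log-odds for immobile
  individuals at level k. Reported as odds exp(γ_k) with Wald CIs and a
  Wald p against odds 1. There is no global intercept; the K diagonal
  columns of the design sum to 1 row-wise and absorb it (identification).
- w ∈ [0, 1]: relative influence of origin versus destination; w = 0.5
  means equal influence, w = 1 means destination is irrelevant.
- δ: the mobility effect proper — the additional log-odds-ratio of having
  moved, the quantity conventional designs cannot isolate. The default
  model includes a downward indicator; an upward or both-indicator variant
  is available (`DRMSpec.mobility_covariate`).
- x: centred age (per year), native (0/1), marital-status dummies against
  the no-partner reference; case weights multiply log-likelihood
  contributions throughout.

The weighted combination is applied on the **log-odds scale**, inside the
link. Expository accounts of DRMs sometimes interpolate the odds directly
(0.35·0.41 + 0.65·0.73 = 0.618); on the link scale the same cell gives
exp(0.35·log 0.41 + 0.65·log 0.73) ≈ 0.597. The two disagree numerically;
the model uses the link scale so that the generative model, the fitted
model and GLM theory coincide, and `interpolate_odds` reproduces the
odds-scale arithmetic for comparison with such accounts.

## Estimation

Conditional on w the DRM is an ordinary weighted logistic GLM, so:

1. **Inner solver** — weighted IRLS/Newton with step-halving; converged
   when max |score| < 1e-8 or relative log-likelihood change ≤ 1e-10.
   Separation is flagged when a coefficient exceeds 15 on the logit scale;
   rank-deficient designs raise.
2. **Profile search** — the profile log-likelihood is evaluated on a
   21-point grid over [0, 1], refined by bounded Brent search in the
   bracketing interval (xatol 1e-6), then polished by a symmetric
   three-point parabolic step (h = 1e-4). The polish makes ŵ invariant
   (to ~1e-7) under transposing origin and destination, where the profile
   mirrors exactly; the returned ŵ maximizes the profile over every point
   evaluated. The optimizer works on [0, 1] directly, so boundary solutions
   ŵ = 0/1 are attainable and flagged.
3. **Inference** — the variance matrix is the inverse negative numerical
   Hessian (central differences, relative step 1e-5) of the full
   log-likelihood in (γ, w, β) at the optimum. Wald 95% CIs throughout;
   the CI for w is unconstrained and may extend outside [0, 1]. No p-value
   is reported for w: a Wald test of an interval-constrained weight against
   zero is invalid; `test_w_against(fit, 0.5)` provides the meaningful
   supplementary test, and refuses boundary or flat fits.

Degenerate cases: all-diagonal data raise (w unidentifiable); a perfectly
flat profile (e.g. balanced outcomes in every cell) returns the midpoint of
the argmax set with a flat flag; if the full Hessian is not negative
definite (boundary/flat), the fit falls back to the conditional-on-w
covariance for (γ, β) with SE(w) = NaN and a `vcov_conditional` flag.

A linear (identity-link) DRM for continuous outcomes uses the same
machinery with a weighted-least-squares inner solver; it is exercised by
unit tests only.

## Conventional designs and the rank-deficiency demonstration

`fit_mobility_group_model` (eight cell dummies vs the always-advantaged
immobile-high group) and `fit_origin_control_model` (upward/downward vs
immobile, controlling origin) are fitted with statsmodels' binomial GLM
using frequency weights; the package's own IRLS solver serves as an
independent cross-check in the tests, and row order and reference
categories mirror the standard table layouts.

`demonstrate_linear_dependency` builds the infeasible design — intercept,
origin and destination position dummies, and a linear mobility score
(destination rank − origin rank) — and reports its rank and dependent
column sets. The score is an exact linear combination of the position
terms, so the design is structurally rank deficient on any table containing
all levels; this is the algebraic reason "mobility controlling for origin
and destination" cannot be estimated. Replacing the score with
upward/downward indicator dummies restores full rank on a 3×3 table (the
indicators are not additive in origin and destination) — such models are
estimable, but their "mobility" terms remain reparameterized
origin–destination contrasts, which is the statistical conflation the
simulation study quantifies. Both codings are exposed.

## Synthetic cohorts

The generator emulates a national mobility survey of adults aged 18–45:

- (origin, destination) drawn from the published 3×3 cell frequencies
  (male n = 1569, female n = 1771) normalized to probabilities;
- outcomes from the logistic DRM surface with the published diagonal odds
  and w (males 0.73/0.74/0.41, w = 0.35; females 0.98/0.55/0.31, w = 0.32)
  and mobility effects δ = 0 — the null world;
- age truncated-normal on [18, 45] with scale 6.88 and the location solved
  (Brent) so the *post-truncation* mean equals the configured 34.95 —
  plain truncation at location 34.95 would shift the realized mean to
  ≈ 34.07, breaking the documented marginal; age is then mean-centred;
- native ~ Bernoulli(0.526); marital status categorical
  (0.191/0.564/0.170/0.075);
- covariate effects default to zero so structure tests are unconfounded; a
  "realistic" preset sets them near the published covariate ORs (age 1.05
  per year, native 0.68, marital 2.38/1.42/1.36).

Reproducibility: one master seed expands to per-replicate substreams via
`numpy.random.SeedSequence.spawn`, so replicates are independent and
individually reproducible.

What the generator does **not** emulate: the survey's two-stage municipality
sampling and oversampling of specific origin groups (weights are exercised
through synthetic weight columns instead), item nonresponse processes,
self-report measurement error in height/weight, or any dependence of the
outcome on cell membership beyond the DRM surface. Passing tests therefore
show that the estimators behave correctly *when the DRM is the truth*; they
do not validate the DRM's substantive adequacy for any real cohort.

## Simulation studies

- **Type-I / conflation study** (default 1000 replicates at n = 1569): data
  from the null DGP; the DRM rejects when its δ covariate has p < α = 0.05;
  the group design when any of the six mobile-group dummies does (with a
  Holm-adjusted variant, since the unadjusted family-wise rate inflates
  even an honest baseline — both are reported); the origin-control design
  when either mobility-status term does. Replicates whose fit fails are
  excluded from rate denominators and counted separately (a failed fit is
  not a decision). Every decision is recomputable from the per-replicate
  archive.
- **Recovery study** (200 replicates at n = 50,000 for the headline run):
  bias, RMSE and 95%-CI coverage of ŵ, the diagonal odds and δ̂.
- **Power study**: DRM rejection rate over grids of δ and n.

When the fitted models contain no individual-level covariates, each
replicate is collapsed to the 18 (cell × outcome) weighted rows before
fitting — exact for case-weighted likelihoods, and what makes the study
sizes above run in about a minute on one CPU.

## Data handling choices

- ISCED collapse: 1–2 → low, 3–4 → medium, 6–8 → high. Codes 0 and 5 fall
  outside the collapse; defaults (0 → low, 5 → high: short-cycle tertiary
  is tertiary) are applied with a warning and are configurable, so the
  choice is always auditable.
- Parental (origin) education: highest of the two parents; father-only as
  a sensitivity variant.
- Eligibility: age ≥ 18 (self-reported BMI as an overweight screen is not
  valid for minors), not enrolled in education (destination not yet
  final), then listwise deletion of missing origin/destination/outcome/
  covariates, with all removals reconciled in a `FilterReport`. No BMI
  cleaning beyond the ≥ 25 threshold; no imputation.
- Mobility tables report unweighted respondent counts; weights enter the
  fitters, not the tables.
- Sex-stratified analysis is a pipeline-level split, not a covariate.

## Known limitations

- Two generations only: the diagonal-reference construction has no
  analogue for three-generation trajectories.
- One symmetric w for all off-diagonal cells; no level-specific weights,
  status-inconsistency extensions, or random effects.
- Wald inference for w near the boundary is unreliable (flagged, not
  patched); a profile-likelihood CI for w is a natural extension not yet
  implemented.
- The conflation rates quantified by the study are specific to the
  configured gradient and table margins; they are operating
  characteristics of the designs under this DGP, not universal constants.
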