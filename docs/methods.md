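# Methods

## The model

`mgwrlab` analyses a county-style ecological table — one row per spatial
unit with coordinates, a population weight, a continuous outcome rate and
covariates — under three nested models.

**Global OLS.** All variables are z-scored (sample SD), so estimates are
standardized effects and the intercept is ~0. Collinearity is screened with
variance inflation factors, VIF_j = 1/(1 − R²_j).

**GWR.** At each unit *i* the coefficients are re-estimated by weighted
least squares, β̂_i = (X′W_iX)⁻¹X′W_iy, with adaptive bi-square kernel
weights w_ij = (1 − (d_ij/b_i)²)² for d_ij < b_i and 0 otherwise, where b_i
is the distance to the *k*-th nearest unit. The bandwidth is the neighbor
count *k*, shared by all covariates, selected by minimizing AICc.

**MGWR.** The multiscale model relaxes the shared-bandwidth assumption:
y = Σ_j f_j + ε, each additive term f_j a local regression on one variable
with its own bandwidth. Calibration is by back-fitting: cycle over terms,
fit the partial residual e_j = y − Σ_{l≠j} f_l on x_j with a univariate
GWR whose bandwidth is re-optimized (AICc, golden-section over integers)
every sweep, until the score of change of the fitted values,
SOC-f = √(mean(Δŷ²)/mean(ŷ²)), drops below tolerance.

Terms without real spatial structure sit on AICc profiles that are flat
(spread well under one AICc unit) over most of the bandwidth range, so
their literal argmin is sampling noise and wanders between seeds. After
the back-fitting loop converges, each term's bandwidth is therefore lifted
once to the largest bandwidth whose AICc lies within 2 units of its
minimum — the conventional equivalence band for AIC-family scores, here
resolved toward the most parsimonious (fewest effective parameters, i.e.
smoothest) member. Terms with genuine regional or local structure pay tens
to hundreds of AICc units for over-smoothing and are left untouched; in
the synthetic validation the fixed-point gap between the argmin and the
maximum bandwidth is ≤ ~2 for spatially constant terms and ≥ ~2.4 (often
≫ 10) for gradient and bump terms, which is what makes the band
discriminating. The full-model GWR bandwidth search (`select_bandwidth`)
keeps plain argmin semantics.

Bandwidths are then
frozen, and the per-term smoothers S_j are composed into hat contributions
R_j (f_j = R_j y) by iterating R_j ← S_j(I − Σ_{l≠j}R_l) to its fixed
point. These give the per-variable effective number of parameters
ENP_j = tr(R_j) — which sum exactly to the total hat trace — and the local
standard errors Var(β̂_ij) = σ̂²[R_jR_j′]_ii / x_ij², σ̂² = RSS/(n − tr S).

All three models share one AICc,

    AICc = 2n·ln σ̂ + n·ln 2π + n(n + tr S)/(n − 2 − tr S),  σ̂² = RSS/n,

with tr S = k+1 for OLS, so the model-comparison column is internally
consistent.

**Inference.** Because each variable's surface involves ENP_j dependent
local tests, the local critical value is taken at the adjusted level
α_j = α/ENP_j (two-sided, df = n − tr S). A `nominal` policy (plain α) is
available by flag, since published significance maps do not always state
which convention they use.

**Monte Carlo non-stationarity test.** Per variable, the observed statistic
is the variance of its local coefficients across units. Coordinates are
permuted among units (data fixed), the model re-calibrated by
frozen-bandwidth back-fitting, and p = (1 + #{perm ≥ obs})/(1 + n_perm).
Holding bandwidths at their fitted values is a deliberate economy: full
re-selection per permutation multiplies cost ~15× while testing the same
null of exchangeable coordinates at the fitted scales.

## The three-dimension disparity framework

- **Level of influence**: the population-weighted share of units where a
  covariate's local estimate is significant; >50% ⇒ *primary* influencer,
  otherwise *secondary*.
- **Scalability**: bandwidth relative to n — >75% ⇒ *global*, <25% ⇒
  *local*, the closed interval [25%, 75%] ⇒ *regional*. The boundary
  convention is by-the-letter of the strict "> 75" / "< 25" wording;
  `scalability_conflict` flags externally reported labels that disagree
  with the rule instead of reproducing them.
- **Specificity**: within each unit, the covariate with the largest
  |standardized local coefficient| (direction ignored) is *dominant*. All
  covariates compete regardless of significance — published dominance
  counts partition the full county set, implying no significance filter —
  so counts always sum to n. Ties break to the first column and are logged.
  The intercept is listed in scalability but excluded from influence and
  specificity.

## Composite indices

`pca_index` builds a deprivation-style index as the first principal
component of column-standardized inputs (correlation-matrix PCA, since the
blocks mix percentages and logged incomes). Loadings are reported as
input–score correlations, matching the conventional "loading > 0.65"
reading, and the eigenvector sign is fixed by requiring a named anchor
variable's loading to be positive (e.g. higher poverty ⇒ higher isolation).
`mean_index` is the plain mean of standardized inputs (residential
stability). Rotations and multi-component retention are out of scope.

## The synthetic generator

Real beneficiary-level data are restricted, so validation runs on
synthetic datasets drawn from the exact data-generating process the local
model family assumes: y_i = Σ_j β_j(s_i)x_ij + ε_i with i.i.d. Gaussian
noise. Three surface kinds encode the three spatial scales: `constant`
(global), `gradient` (regional; an affine trend along a direction, scaled
to span one unit across the study area so slopes are comparable across
layouts), and `bump` (local; a bi-square-shaped pocket of radius r). Unit
populations are log-normal, rounded, floored at 1 — county beneficiary
counts are strongly right-skewed and the influence dimension needs unequal
weights. Covariates are drawn jointly normal (equicorrelation 0.3 by
default) and z-scored at generation; the intercept surface is simulated
like any covariate, since empirical multiscale fits give the intercept its
own (often small) bandwidth.

Default preset: n = 400 units, uniform-random over a 100×100 area, six
covariates (2 constant, 2 gradient, 2 bump with heights 2.0 and −1.5 and
radii 40/35), noise SD 0.5, seed 11. The sizes are desk-scale: large
enough that constant/gradient/bump surfaces select clearly separated
bandwidths, small enough that a full fit takes seconds. The bump amplitude
(~1.7 on the standardized scale) is comparable to the spread of local
estimates reported for risk-score covariates in county studies. With this
noise level the standardized noise SD is ~0.42, so a local slope estimated
from ~38 neighbors has a variance floor near 0.12 — recovery RMSE for the
bump surfaces therefore sits around 0.12–0.17 across seeds, dominated by
the smoother, not by implementation error.

What the generator does **not** emulate: real county geography and
adjacency, spatially autocorrelated noise (ε is i.i.d. by construction),
skewed/sparse outcomes, and measurement error in covariates. Passing tests
show the estimator recovers the multiscale structure it assumes; they do
not certify behavior under model misspecification.

## Numerical choices

- Bandwidth search over integers in [10, n] by default (golden-section,
  exhaustive below 64 candidates; ties resolve to the smaller bandwidth).
  The lower cap of 10 neighbors keeps univariate local fits stable.
- Self is included in the neighbor count with weight 1; units exactly at
  the bandwidth distance get weight 0 (open kernel support).
- SOC-f tolerance 1e-5, max 200 selection sweeps; the hat-matrix recursion
  runs to a 1e-10 fixed point or 100 sweeps.
- ENP below 1 is clipped to 1 in the α correction (with a warning).
- Local R² uses the same kernel weights as estimation; for MGWR, which has
  no single bandwidth, the median selected bandwidth is used as the
  goodness-of-fit mapping scale.
- Degenerate inputs fail loudly: constant variables, duplicate unit ids or
  coordinates, non-positive-definite covariate correlations, singular
  local designs (reported with the focal unit and variable).
- Distances are dense n×n (euclidean, or haversine kilometres when
  coordinates are lon/lat); fine for the ≤ ~5,000 units this package
  targets.

## Known limitations

- Continuous-outcome MGWR only; heavily skewed or sparse rates would need
  a count-model extension.
- The Monte Carlo test's frozen-bandwidth scheme slightly understates the
  variability of the full selection pipeline.
- Local collinearity among terms is not diagnosed beyond the global VIFs.
- Global estimates do not decompose into the local ones; the two model
  readings are reported side by side, not reconciled.
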