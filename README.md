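# mgwrlab

Multiscale geographically weighted regression (MGWR) for county-level
health-disparity analysis.

Ecological health outcomes — e.g. an opioid-use-disorder rate per 1,000
beneficiaries in each US county — rarely relate to their covariates the
same way everywhere. `mgwrlab` is for spatial epidemiologists and health
geographers who want to ask not just *whether* a county characteristic is
associated with an outcome, but *where*, and *at what spatial scale*. It
provides:

- a from-scratch **MGWR engine**: adaptive bi-square kernels, AICc
  bandwidth selection by golden-section search, back-fitting with a
  per-variable bandwidth, per-variable effective parameters (ENP) with
  corrected local inference, and a Monte Carlo test for spatial
  non-stationarity;
- a **global OLS baseline** with VIF diagnostics and a shared AICc so the
  models are directly comparable;
- **composite-index construction** (first-component PCA deprivation-style
  indices with anchored sign, mean-of-z scales);
- the **three-dimension disparity framework**: level of influence
  (population-weighted share of units where a covariate is locally
  significant; >50% ⇒ primary), scalability (bandwidth >75% of n ⇒ global,
  <25% ⇒ local, else regional), and specificity (each unit's dominant
  covariate by |standardized local coefficient|);
- a **synthetic county-data generator** with known constant / gradient /
  bump coefficient surfaces, so every stage is validated against ground
  truth without restricted data.

## The model

With units i = 1..n at locations s_i, GWR calibrates
y_i = Σ_j β_j(s_i) x_ij + ε_i locally:

    β̂(s_i) = (X′W_i X)⁻¹ X′W_i y,
    w_ij = (1 − (d_ij/b_i)²)²  for d_ij < b_i  (adaptive bi-square),

where b_i is the distance to the k-th nearest unit and the bandwidth k
minimizes AICc. MGWR generalizes this to an additive model y = Σ_j f_j + ε
in which every term has its *own* bandwidth, fitted by back-fitting on
partial residuals; per-term hat contributions R_j give ENP_j = tr(R_j),
local standard errors, and the α/ENP_j-corrected local t tests. See
`docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from mgwrlab import default_config, simulate_dataset, fit_ols, fit_mgwr, dimension_report

data, truth = simulate_dataset(default_config(seed=11))  # 400 units, 6 covariates
ols = fit_ols(data)
res = fit_mgwr(data)
print(f"AICc  OLS {ols.aicc:.2f}  MGWR {res.aicc:.2f}")
print(dict(zip(res.names, res.bandwidths.tolist())))
report = dimension_report(res, data)
print(report.table[["variable", "bandwidth", "scalability_class",
                    "influence_class", "dominance_share"]].to_string(index=False))
```

prints

```
AICc  OLS 943.25  MGWR 588.48
{'intercept': 400, 'x1': 400, 'x2': 400, 'x3': 143, 'x4': 235, 'x5': 38, 'x6': 38}
 variable  bandwidth scalability_class influence_class  dominance_share
intercept        400            global                             0.00
       x1        400            global         primary            51.00
       x2        400            global         primary             0.00
       x3        143          regional         primary             5.25
       x4        235          regional         primary             0.00
       x5         38             local       secondary            26.50
       x6         38             local       secondary            17.25
```

The two covariates generated with spatially constant effects (x1, x2)
select the maximal bandwidth and classify as global-scale processes; the
two gradient covariates land in the regional band; and the two bump
covariates — whose effect is concentrated in one pocket of the study area
— select 38-neighbor bandwidths and classify as local. The bump covariates
are *secondary* influencers (their estimates are significant only inside
the pocket, covering less than half the population) yet dominate the
specificity dimension wherever the pocket is active, while the constant
covariate x1 is a *primary* influencer (significant everywhere) and
dominant in about half the units — exactly the dissociation between
"affects many people" and "strongest where it acts" the framework is
designed to expose. MGWR's AICc beats the global OLS model by ~355 points
on these heterogeneous data, the same ordering such county analyses
report.

The same pipeline runs from the shell:

```sh
mgwrlab simulate --out sim --seed 11
mgwrlab run --out results --seed 11 --n-perm 99
```

which writes descriptives, the OLS table, per-unit local estimates with
significance flags, local R², the Monte Carlo report, the three-dimension
table and per-unit dominant covariates as headed CSVs (plus a MANIFEST and
a config echo). `mgwrlab fit-ols / fit-gwr / fit-mgwr / montecarlo /
dimensions` run individual stages on your own CSV or GeoJSON point file.

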