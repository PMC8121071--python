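# mahaniche

Virtual-ecology experiments on Mahalanobis-distance ecological niche
models: which multivariate location/scatter estimator should a
presence-only modeller use, and how does that choice interact with
occurrence sample size, record errors, and sampling bias?

## The problem

A Mahalanobis-distance niche model needs only an m×n matrix of species
occurrences in environment space. From a location vector and scatter
matrix it computes

    D²(x) = (x − μ̂)ᵀ Σ̂⁻¹ (x − μ̂),

and since D² of multivariate-normal data follows a χ²_n distribution,
P(χ²_n > D²) estimates the probability that environment x lies inside
the species' fundamental niche. Three estimators of (μ̂, Σ̂) are in
common use:

* the **sample** means and variance-covariance matrix;
* the **minimum covariance determinant** (MCD): the h-point subset with
  the smallest covariance determinant;
* the **minimum volume ellipsoid** (MVE): the smallest ellipsoid
  covering h points.

MCD and MVE are robust to the outliers that record errors produce — but
natural-history data also carry strong sampling bias, which robust
estimators can mistake for the signal and lock onto. The retained
proportion k = h/m (k ≈ 0.55 most robust, k → 1 classical) controls the
trade-off.

This package simulates a virtual species with a known elliptical niche
(growth rate λ_F, optimum at 7.5 °C / 1800 mm), generates
detection-filtered occurrence samples, contaminates them with errors
(uniform draws from a synthetic regional climate space) or bias
(detection-weighted draws), fits all three estimators, and scores each
fit by the correlation between the true λ_F and the modelled
P(χ²₂ > D²) at the sampled points, replicated over conditions. See
`docs/methods.md` for the full model description.

## Worked example

```
$ python analysis/01_idealised_model.py --seed 1
Idealised sample: m=100, mean environment = (7.32 degC, 1852 mm) vs optimum (7.5 degC, 1800 mm)
  sample  r(lambda_F, P(chi2_2 > D^2)) = 0.9588
  mcd     r(lambda_F, P(chi2_2 > D^2)) = 0.9524
  mve     r(lambda_F, P(chi2_2 > D^2)) = 0.9631
All three methods track the true niche closely on clean data.
```

With a clean, detection-filtered sample of 100 occurrences every
estimator ranks environments almost exactly as the true niche does
(r > 0.95). The interesting behaviour appears under contamination:

* `analysis/02_sample_size.py` — at m = 10 the classical estimator
  clearly beats MCD/MVE at k = 0.55; the gap fades by m ≈ 55.
* `analysis/03_sample_error.py` — with 30% random regional records the
  robust methods beat the classical estimator by ~0.3 in median r.
* `analysis/04_sample_bias.py` — with ≥ 50–60% biased records the
  classical estimator beats MCD at k = 0.55, and the penalty vanishes
  at k = 0.95.

Each driver prints per-condition median correlations and writes tidy
summary tables under `results/`. The library equivalent:

```python
from mahaniche import ExperimentConfig, run_experiment

cfg = ExperimentConfig(mode="error", reps=50, seed=1)
res = run_experiment(cfg)
print(res.summary.head())
```

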