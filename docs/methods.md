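# Methods

This note documents the models, algorithms and design choices behind
`mahaniche`: a virtual-ecology study of how the choice of multivariate
location/scatter estimator affects Mahalanobis-distance niche models
under varying occurrence sample size, error contamination, and sampling
bias.

## The virtual species

The fundamental niche is an elliptical Gaussian in a two-dimensional
climate space of mean annual temperature (°C) and annual rainfall (mm).
The finite rate of increase at environment **x** is

    λ_F(x) = λ_max · exp(−½ (x − μ)ᵀ Σ⁻¹ (x − μ))

with defaults λ_max = 2.5, μ = (7.5, 1800), Σ = [[2, −950], [−950,
800000]] — a montane species whose cooler sites tend to be wetter
(correlation ≈ −0.75). The quadratic form is evaluated by a Cholesky
solve rather than an explicit inverse; both agree to 1e−10 on the
defaults (tested).

Detection is logistic in the growth rate,

    P_d = 1 / (1 + exp(−10 (λ_F − 0.5))),

near zero where the population cannot persist and saturating near one
above replacement. Note the logistic floor: P_d(0) ≈ 0.0067, so
detection-weighted rejection sampling is never literally impossible,
only slow; an attempt cap (10⁶) converts pathological cases into an
explicit error.

## Estimators

All three estimators summarise an m×n occurrence matrix by a location
vector and scatter matrix feeding D²(x) = (x − loc)ᵀ scatter⁻¹ (x − loc)
and the chi-squared probabilities P(χ²_n ≤ D²) / P(χ²_n > D²).

* **sample** — column means and the (m−1)-denominator covariance.
* **MCD** — the h-point subset with the smallest covariance
  determinant. Fast mode is the FAST-MCD scheme: elemental (n+1)-point
  starts (extended by random points while singular), two concentration
  steps each, full concentration of the ten best candidates, smallest
  determinant wins. A concentration step retains the h points of
  smallest D² under the current estimate and re-estimates; the
  determinant is provably non-increasing (asserted per step in tests).
  When the number of distinct elemental subsets is at most `n_trials`
  they are all enumerated deterministically, which makes fast mode exact
  on small fixtures. Exhaustive mode enumerates every h-subset (capped
  at 10⁶ subsets) and serves as a brute-force oracle.
* **MVE** — the minimal-volume ellipsoid covering h points, by the
  classical resampling algorithm: each elemental subset proposes a shape
  (mean c, covariance C); the inflation λ is the h-th smallest D² of the
  full sample under (c, C); the candidate minimising det(C)·λⁿ wins, and
  the raw scatter is λ·C.

Subset sizes follow h = ⌊k·m⌋ for a user proportion k ∈ (0.5, 1], else
the maximally robust default h = ⌊(m+n+1)/2⌋, clamped to [n+1, m]. The
floor carries a 1e−9 additive guard because k·m may land just below an
integer in binary floating point (0.95·20). MCD requires m ≥ 5n; MVE
only h ≥ n+1. Subset covariances use the h−1 denominator throughout.
Ties in "h smallest distances" break to the lowest row index (stable
sort); ties in the objective keep the first candidate found. Everything
is deterministic given the seed.

### Reweighting (default) and raw modes

By default both robust estimators apply the one-step reweighting that
classical robust-covariance software applies after the subset search:
the best-subset covariance is inflated by (1 + 15/(m−n))², distances of
all m points are computed under it, and the final location/scatter are
the plain mean/covariance of the points with

    D² < χ²_n(0.975) · quantile(D², h/m) / χ²_n(h/m).

This recovers near-classical efficiency on clean data — raw subset
estimates at k = 0.55 distort the fitted shape enough to pull the
idealised-sample correlation from ~0.96 down to ~0.81 — while still
excluding gross outliers, and it is what makes the error/bias trade-off
of the experiments interpretable. At h = m the cut degenerates and the
robust estimators reduce to the classical one, so reweighting is
skipped there (MCD at h = m is then bit-identical to the sample
estimator).

With `reweight=False` the raw subset estimates are returned; the
`rescale` toggle then applies a chi-squared consistency factor so D²
quantiles match the normal model: for MCD the scatter is multiplied by
median(D² of retained points)/χ²_n(0.5); for MVE it is divided by the
χ²_n(h/m) quantile (continuity-corrected to (m−0.5)/m at h = m, where
the raw quantile would be 1 and the factor unbounded). Raw mode is what
the exhaustive-oracle and affine-equivariance tests exercise, since the
reweighting cut is not affine-equivariant in its point count.

## Synthetic regional climate space

The error/bias experiments need a finite set of available regional
climates (emulated grid cells of a climatology). It is drawn from a
two-component bivariate-normal mixture truncated to hard bounds
(temperature −2..16 °C, rainfall 50..6000 mm), N = 4000 cells with
uniform weights:

* dominant component (80%): mean (4.5 °C, 700 mm), SDs ≈ (2.2 °C,
  600 mm) — common climates far from the niche optimum in the
  cool/dry direction;
* minor component (20%): mean (8.3 °C, 1250 mm), SDs ≈ (1.3 °C,
  500 mm) — climates overlapping the low-rainfall flank of the niche.

These defaults were fixed once against two structural requirements and
then frozen: fewer than 30% of cells have P_d > 0.5 (uniform draws are
mostly low-detection environments, so errors represent the region rather
than the niche; measured ≈ 0.26 across seeds), and the density mass sits
off-centre from μ (biased draws concentrate on one flank; the biased
mean environment is ≈ (7.9 °C, 1300 mm) against μ = (7.5, 1800)).
Cells are sampled uniformly by cell, not by any notion of area, and the
space is a finite point set — no spatial autocorrelation, geographic
structure, or raster I/O. A user-supplied space can be loaded from a
CSV of temperature/rainfall (optional weight) columns.

What the generator does *not* emulate: real climatologies have strongly
non-Gaussian, spatially autocorrelated climate distributions, and real
occurrence bias follows roads and observers rather than a clean
detection filter. Passing experiments therefore demonstrate the
estimators' behaviour under the idealised mechanisms of error and bias,
not performance on any particular real data set.

## Sampling and contamination

Idealised samples: rejection sampling from N(μ, Σ) with acceptance
probability P_d (acceptance ≈ 0.80 under the defaults). Contamination
uses replacement semantics — round(e·m) rows become uniform space draws
("error"), round(b·m) rows become detection-weighted draws ("bias"),
positions chosen uniformly without replacement — so the sample size m
stays fixed and the contamination level is the only moving part.
Rounding is half-up, exact on the experimental grids at m = 100. The
experiments never combine error and bias, though the API allows it.

## Experiments

One experiment = one mode (size / error / bias) × a condition grid ×
replicates. Per replicate: generate the sample (idealised at m for size
mode; idealised at m = 100 then contaminated for error/bias), fit the
classical estimator once and MCD/MVE at each k ∈ {0.55, 0.75, 0.95},
and score each fit by the Pearson correlation between λ_F(xᵢ) (truth)
and P(χ²₂ > D²(xᵢ)) (model) over the sample's own points. Spearman is
available as a sensitivity flag; the transform is monotone in D², so
the two flavours differ by < 0.05 in practice (tested). Methods are
paired — all score the same sample.

Seeding is splittable: replicate r of condition index c uses
`SeedSequence([seed, mode_code, c, r])`, with children spawned for
sample generation, contamination and each robust fit, so any replicate
reruns in isolation. Degenerate fits and undefined correlations are
recorded as failed replicates (NaN), excluded from quantiles, and
counted in the summary; they do not abort a run. Summaries are medians
and quartiles with the linear-interpolation convention, verified in
tests against an independently written quantile routine.

Defaults reproduce the full design (500 replicates); the analysis
drivers and acceptance tests run the scaled-down design at 50
replicates per condition, which keeps each driver in the minutes range
while leaving the qualitative orderings stable (margins of 0.03–0.15 in
median r at the checked conditions).

## Known limitations

* Two environmental dimensions in all defaults and experiments; the
  code is dimension-general but untested beyond small n.
* No deterministic-MCD variant, no large-m partitioned search.
* The reweighting cut makes retained-point counts data-dependent, so
  `retained_indices` under the default configuration is the reweighted
  selection, not an h-subset; raw mode restores the h-subset semantics.
* The performance metric is evaluated at the sample's own (possibly
  contaminated) points, matching the experimental design; it is not a
  map-wide accuracy measure.
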