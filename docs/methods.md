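# Methods

## Problem and model

Daily reference evapotranspiration ET0 (mm d⁻¹) — the water demand of a
well-watered reference grass surface — is the anchor quantity for irrigation
scheduling. The benchmark estimate is the FAO-56 Penman–Monteith combination
equation, which needs five meteorological inputs: minimum and maximum air
temperature (Tmin, Tmax, °C), wind speed at 2 m (Ws, m s⁻¹), mean relative
humidity (Rh, %), and solar radiation (Sr, MJ m⁻² d⁻¹). In data-poor regions
only subsets are available; this package estimates ET0 from any of eight
input combinations C1–C8 — the always-paired temperature base (C1) plus
every subset of {Ws, Rh, Sr}.

The estimator is a *quasi-fuzzy* neural hybrid. Each input variable is
fuzzified into three linguistic labels (low / medium / high) by symmetric
triangular membership functions anchored at the training minimum `l`,
midpoint `m = (l+h)/2` and maximum `h`. For a k-variable combination the
rule base is the complete Cartesian product of label assignments (3^k
rules; 9, 27, 27, 27, 81, 81, 81, 243 for C1..C8, 576 in total) — no rule
selection, pruning, or expert judgement. Every rule fires on every record
through the product t-norm (the product of its labels' membership degrees),
and the firing strengths, normalized to sum to one, form the *interim
vector*. That vector — not a defuzzified scalar — is the input to a
one-hidden-layer perceptron with a linear output unit, trained by L-BFGS
on squared error against Penman–Monteith targets. One head is trained per
combination; the fuzzification (one partition per variable, fit on the
training split only) is shared across combinations.

Two printed-form corrections are built in deliberately. The medium label's
falling branch uses denominator `(h − m)`, keeping the triangle continuous
and symmetric, and the medium peak sits at the midpoint `(l+h)/2`; together
they give a partition of unity (μ_low + μ_medium + μ_high = 1 everywhere).
A consequence: with these default partitions the firing strengths of a
full Cartesian rule base already sum to 1, so normalization is a
mathematical identity; it is kept because user-supplied (expert-elicited)
partitions need not satisfy it. Outside the fitted range `[l, h]` the
nearest extreme label saturates at degree 1, so test-time values beyond
the training extremes still produce a live interim vector — the design
answer to the out-of-range failure mode of grid-partition neuro-fuzzy
systems, which can fire no rules at all on unseen data.

## The Penman–Monteith engine

The target ET0 is computed from the five variables by the standard FAO-56
formulation: ET0 = [0.408 Δ (Rn − G) + γ (900/(T+273)) u₂ (es − ea)] /
[Δ + γ (1 + 0.34 u₂)], with daily soil heat flux G = 0, T the mean of the
temperature extremes, es the mean saturation vapour pressure at the
extremes, ea = Rh/100 · es, and Rn the net radiation from the usual solar
geometry (extraterrestrial radiation from day of year and latitude,
clear-sky ceiling Rso = (0.75 + 2·10⁻⁵ z) Ra, albedo 0.23, Stefan–Boltzmann
net longwave with humidity and cloudiness corrections). The combination
equation uses *net* radiation Rn, not extraterrestrial Ra. Numerical
guards: the cloudiness ratio sr/Rso is clamped to [0.05, 1] inside the
longwave term so overcast or degenerate days cannot blow it up; radiation
exceeding Rso by more than 5 % triggers a warning. Negative computed ET0
(possible only for hot, saturated, dark days under the clamp) is returned
as computed; `floor_at_zero=True` clamps it. Wind is assumed measured at
2 m; no height conversion is applied. The engine is verified against an
independently coded reference implementation (in R, from the same handbook
equations) to ~10⁻¹² mm d⁻¹ on randomized physical inputs.

## Training and selection

Heads are fit with scikit-learn's L-BFGS solver (quasi-Newton steps
w_{k+1} = w_k + η_k d_k, d_k = −H_k ∇E(w_k), limited-memory inverse-Hessian
estimate), seeded small random initial weights, default iteration cap 400
and tolerance 10⁻⁶. Hidden size and activation are chosen by k-fold
(default five-fold) cross-validated MSE over a grid; folds are contiguous
and unshuffled because the data are chronological. Ties break toward fewer
hidden units, then the fixed activation order (identity, logistic, tanh,
relu). The full default grid is hidden ∈ {2..16}; the standard benchmark
(below) uses the subset {4, 10, 16} × {tanh, relu}, which keeps a complete
eight-combination run on one CPU at a few minutes without changing the
selection machinery. After fitting, weights are extracted into plain
arrays and prediction is an explicit forward pass, so persisted models
(JSON bundles with a SHA-256 payload checksum; floats stored with
shortest round-tripping repr) reproduce predictions bitwise.

Baseline comparators (optional rows in the experiment table) follow common
practice for this problem: a CART regression tree grid-searched over depth
2–16 and cost-complexity pruning strength in [0, 1], and a one-hidden-layer
network on the raw (unfuzzified, standardized) variables over the same
hidden range — both five-fold on the training split.

## Synthetic weather testbed

The generator emulates the humid/sub-humid plains of northern West Bengal
(~26.4 °N, ~80 m a.s.l.): Tmax as an annual sinusoid (mean 28.5 °C,
amplitude 3.5 °C, peak in early August) with clipped Gaussian noise; Tmin
as Tmax minus a winter-peaking positive diurnal range; relative humidity
as a wet-season-peaking sinusoid clipped to [20, 100] %; wind speed as
Weibull(k = 1.7, λ = 1.34 m s⁻¹), giving a ~1.2 m s⁻¹ mean and guaranteed
positive skewness; and radiation as a dry-season-peaking clearness
fraction in [0.25, 1] of the site's clear-sky ceiling, so sr ≤ Rso by
construction. All draws come from one seeded generator in fixed order, so
a seed fully determines the series.

What the testbed does *not* emulate: day-to-day weather persistence
(autocorrelation), cross-variable dependence beyond the shared seasonal
cycle (e.g. humid days being duller), monsoon onset sharpness, and
multi-year trends. Passing the synthetic benchmark therefore shows that
the pipeline learns a smooth nonlinear ET0 response under realistic
marginal distributions — not that it attains any particular accuracy on
reanalysis or station data.

## Standard benchmark and evaluation

`evatcrop.model.benchmark_experiment(seed)` generates 4,800 synthetic days
(~13 years, comparable to the motivating 2000–2014 record length), labels
them with the Penman–Monteith engine, splits 70/30 chronologically
(training count floored), trains all eight combinations, and evaluates six
metrics per phase: R² (standard 1 − SSres/SStot form; the raw printed
ratio that returns 0 for a perfect fit is available behind
`verbatim=True` for auditability), Willmott's degree of agreement d,
RMSE (mm d⁻¹), RMSRE, and the averages Ag = (R² + d)/2 and
Ae = (RMSE + RMSRE)/2 (mixed units, as defined). Undefined cases —
constant reference for R²/d, any zero reference value for RMSRE — yield
NaN rather than an epsilon substitute. On this benchmark the full input
set (C8) scores test R² ≈ 0.97 and d ≈ 0.99, and the combined goodness
ordering reproduces the qualitative finding that the full set is best and
the temperature-only pair worst; the exact numbers for a given seed are
recomputed by `scripts/acceptance.py`.

## Known limitations

- Accuracy figures from the original three-station reanalysis study are
  not reproducible here; the synthetic benchmark is a scaled stand-in.
- Interim vectors are piecewise-multilinear features; heads cannot
  extrapolate trends beyond the clamped membership plateaus (predictions
  saturate outside the training range rather than growing).
- The 575-vs-576 rule-count discrepancy in the original description is
  resolved in favour of the complete product (576); the package logs the
  count it actually uses.
- Reproducibility is exact for a fixed platform/BLAS; across platforms,
  floating-point differences in L-BFGS may alter low-order digits.
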