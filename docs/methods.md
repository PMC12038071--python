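# Methods

## Model family

All three grey models act on a strictly positive, equally spaced sequence
x⁽⁰⁾(1..n), n ≥ 4, indexed by k (calendar years are metadata only). The
accumulated series y⁽¹⁾ is the cumulative sum of x⁽⁰⁾ (GM, NGBM) or its
r-order fractional generalization (FGM), computed with generalized binomial
weights wⱼ = C(j+r−1, j) via the stable recurrence wⱼ = wⱼ₋₁(j−1+r)/j. The
inverse fractional accumulation applies the order −r weights, which are the
exact convolution inverse; the round trip is exact to ~1e-15.

The discrete grey equation

  x⁽⁰⁾(k) + β₁ z⁽¹⁾(k) = β₂ (z⁽¹⁾(k))^γ,  k = 2..n,

with background value z⁽¹⁾(k) = α y⁽¹⁾(k) + (1−α) y⁽¹⁾(k−1), is solved for
(β₁, β₂) by least squares. Two routes are implemented: the explicit 2×2
normal-equation ratios in the background sums, and a numerical
`numpy.linalg.lstsq` solve; the test suite and acceptance script verify they
agree to better than 1e-8 relative on 1000 random instances. Systems whose
normal matrix exceeds condition number 1e12 are rejected with a diagnostic
rather than silently producing noise.

Prediction uses the closed-form solution of the whitening Bernoulli ODE
dy⁽¹⁾/dt + β₁y⁽¹⁾ = β₂(y⁽¹⁾)^γ through the initial condition
y⁽¹⁾(1) = x⁽⁰⁾(1), then first (or fractional) differencing back to the raw
scale. The k = 1 prediction reproduces the window's first observation
exactly. Consistency of the closed form with the ODE is checked two ways:
against `scipy.integrate.solve_ivp` at tight tolerance, and by
central-difference residuals along the trajectory (≤ 1e-5 relative).

Family relations are exact and tested: NGBM with γ = 0 equals GM at every
operation (≤ 1e-10 relative), FGM with r = 1 equals GM likewise. FGM is
built as r-order accumulation → GM least squares and time response on the
accumulated series → r-order inverse restoration; this is the standard
construction, chosen because the fractional variant is otherwise
underdetermined (other fractional formulations exist and would differ
numerically).

### Degenerate inputs and numerical guards

* γ = 1 makes the Bernoulli ODE linear in log-space and the closed form
  singular; it is excluded by a hard band |γ−1| > 1e-6, and the tuner
  rejects candidates inside the band with an infinite fitness.
* A non-positive bracket under a fractional exponent 1/(1−γ) raises a
  domain error naming the offending index instead of going complex. When
  the exponent is an integer the negative bracket is legitimate and kept.
* β₁ = 0 (no development) is rejected as a degenerate ODE.
* Positivity of the data guarantees z⁽¹⁾ > 0, so z^γ is always real.

## Hyperparameter tuning

The fitness is the in-sample fitted MAPE over k = 2..n of the training
window — fit once per candidate, not rolling — which follows the tuning
procedure's literal formulation (the per-candidate fit is what makes a
50 × 1000 search affordable on 12 points). Decision variables and boxes:
α ∈ [0,1] for all models; γ ∈ [−2, 2] for NGBM (the interesting optima in
applications sit well inside); r ∈ (0, 1] for FGM, implemented as
[1e-6, 1].

The firefly swarm uses the conventional settings as defaults: population 50,
1000 sweeps, absorption γ_abs = 1, step factor 0.01, β₀ = 1, β_min = 0.2.
Design choices where the canonical algorithm leaves room:

* **Minimization orientation** — "brighter" means lower MAPE; each firefly
  moves toward every brighter one in a full pairwise sweep per iteration,
  using the brightness ranking from the previous evaluation; objectives are
  re-evaluated once per firefly per sweep, so the budget is exactly
  population × (sweeps + 1) evaluations.
* **β_min as a floor** — attractiveness is
  β_min + (β₀−β_min)e^(−γ_abs r²), which equals the textbook form at
  β_min = 0 and keeps long-range attraction from vanishing entirely.
* **Best firefly** — takes a pure random-walk step (no brighter target
  exists).
* **Bounds** — positions are clamped to the box after every move.
* **Randomness** — a single seeded NumPy generator; per sweep one
  (N, N, d) block of uniforms indexed (mover, target, dimension) plus an
  (N, d) random-walk block, unused entries discarded. This fixed
  consumption order makes runs bit-identical for a given seed and is much
  cheaper than per-move scalar draws.
* **Warm start** — the tuner replaces the first seeded position with the
  classical default (α = 0.5, γ = 0 / r = 1) after the stream draw (so
  later draws are unchanged). With best-ever elitism this makes "tuned
  never worse than untuned" a structural property rather than a statistical
  one.
* **No early stopping** — the configured sweep count always runs;
  convergence in practice is far faster.

## Rolling evaluation

Hold-out accuracy is one-step-ahead with refitting: at each origin the model
is refitted (hyperparameters frozen from the training-only tuning) on the
trailing `window_length` observations — by default the training length — and
the restored k = window+1 prediction is emitted; the window then absorbs the
realized actual. This is causal by construction (perturbing a later actual
cannot change an earlier forecast — tested). Beyond the data the window
absorbs the model's own predictions instead; both a refit-each-step and a
fit-once mode are exposed, since multi-year extrapolation can reasonably be
run either way. The linear baseline is fitted once on the training block
(OLS of value on time index via statsmodels) and extrapolated, giving the
constant-slope column structure expected of it.

MAPE is always the mean of unrounded APEs; rounding to 2 decimals happens
only in rendered tables. This matters: the published validation aggregate of
the tuned Bernoulli model (2.57%) is reproducible only under full-precision
averaging (rounded APEs would give 2.58%).

### Splitting

`split_series` partitions chronologically with sizes round(f₁n), round(f₂n)
(half-up) and the remainder — the only rounding rule consistent with a
12/5/3 partition of 20 points under 60/25/15. Parts always concatenate back
to the input; a training part shorter than 4 triggers a warning since no
grey model can be fitted on it. The container itself accepts any length
≥ 1 so that short hold-out blocks (the 3-point validation window) remain
first-class series; the n ≥ 4 floor is enforced at fitting and CSV-ingest
time.

## Synthetic data

The generator inverts the prediction path: choose (β₁, β₂, γ), run the time
response forward, restore, and (optionally) multiply by exp(ε),
ε ~ N(0, noise_sd) — multiplicative log-normal noise, because additive noise
could violate the positivity the whole machinery depends on. Defaults
(n = 12 annual points starting 2004, growth-type β₁ < 0) mirror the typical
training-window geometry of the motivating application. One structural
caveat: the k = 1 point is the initial condition, not part of the
exponential-difference law, so trajectories can step down from k = 1 to
k = 2 before growing; tests therefore assert monotonicity from k = 2 on.

What synthetic trajectories do show: exact-recovery behaviour (the tuner
finds a generating exponent to ±0.01 on clean data), reduction identities,
and determinism. What they cannot show: robustness to structural breaks,
reporting artefacts, or level shifts of real administrative data — the
published-record fixture covers the metric arithmetic on real numbers, but
no synthetic test certifies real-data forecast accuracy.

## Problem sizes and runtime

The acceptance script runs the exponent-recovery check at the full
conventional swarm size (50 × 1000, ten runs: two exponents × five seeds),
1000 random instances for the least-squares cross-check, 20 series for the
dominance check, and two full CLI runs for determinism — about 90 seconds
on one CPU. The test suite uses smaller swarms (10–50 fireflies, 20–150
sweeps) wherever the property under test does not depend on swarm scale;
the sphere-benchmark and recovery acceptance tests keep the full
conventional settings.

## Known limitations

* The 2004–2015 Istanbul history exists only as a figure in the source
  material, so the original study's tuned hyperparameters (α = 0.88,
  γ = −0.42; α = 0.53; α = 0.21, r = 0.98) and its 2024–2026 forecasts
  cannot be reproduced numerically; the packaged fixture starts at 2016.
* Fitness is in-sample MAPE, which can overfit the training window for
  strongly noisy series; no information criterion or cross-validation is
  provided.
* No prediction intervals — the models are deterministic point forecasters.
* Single-variable models only; no covariates, no multivariate grey models,
  no alternative metaheuristics.
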