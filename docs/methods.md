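# Methods

## Model and assumptions

Each study i estimates a common true effect θ on an analysis scale with
known sampling variance: y_i = θ + ε_i, ε_i ~ N(0, σ_i²). The analysis
scale is Hedges' g for mean differences and Fisher's z for correlations
(variance exactly 1/(n−3), independent of r). Fixed-effect pooling and a
common θ across the pair are assumed throughout — with only two studies,
between-study heterogeneity can be neither estimated nor tested with any
reliability, so random-effects modeling is out of scope by design.

The original study is assumed to have been *selected on significance*: it
passed a two-tailed test at level α (default .05) in the predicted
direction, i.e. a one-tailed test at α/2. Its observed effect is therefore
a draw from a truncated sampling distribution, and its expected value
exceeds θ regardless of whether publication bias exists. The replication
is assumed unselected. `StudyPair` enforces the selection assumption at
construction and refuses a non-significant original (a `force` flag exists
for exploration; hybrid point estimates are then generally undefined and
reported as NaN).

## The conditional probability engine

The engine evaluates, at any hypothesized θ,

    q_O(θ) = P(y ≥ y_O; θ) / P(y ≥ y_O^CV; θ),      q_R(θ) = P(y ≥ y_R; θ),

where y_O^CV is the selection threshold (independent of θ). Both are
probability-integral transforms at the true θ — q_O with respect to the
truncated distribution — hence uniform on (0, 1) there. Their sum
x = q_O + q_R is monotone non-decreasing in θ and follows the two-term
Irwin–Hall distribution at the true θ. The Irwin–Hall CDF, quantile
function and two-tailed fold G(x) = 2·min(F(x), 1−F(x)) are implemented in
closed form.

Two sampling backends are provided:

- **Noncentral t** (default for mean designs). Probabilities are computed
  on the t scale: tails of t(df, ncp) at the observed t and at the central
  t quantile t_{1−α/2}(df), with ncp = (θ/J)·√(n₁n₂/(n₁+n₂)) for two
  groups (√n for one group), J being the small-sample correction mapping g
  to d. This is the scale on which the studies' tests were actually
  carried out, and it reproduces the reference worked-example values
  (q_O = 0.6, two-tailed p ≈ .56).
- **Normal** (correlations, and the entire analytic evaluation module).
  Tails of N(θ, σ²) on the analysis scale, the standard meta-analytic
  assumption.

The backend is selected automatically from the effect metric and can be
overridden. The two backends disagree slightly for mean designs (the
normal backend gives p ≈ .59 for the worked example); the t backend is
the default because it is exact for the t statistics users supply.

### Numerical tail computation

q_O is a ratio of two tails that both underflow for strongly negative θ,
so it is always computed in log space (`log_ndtr` for the normal backend)
and clipped into [1e−300, 1]. For the noncentral t, scipy's Boost-based
`nct.logsf` is accurate down to tail masses of roughly 1e−11 but then
oscillates (returning −inf, −0.0, or finite-but-wrong values). Below that
trust floor the tail is computed by direct log-space quadrature of the
mixture representation P(T ≥ t) = E_W[Φ̄(tW − ncp)], W = √(χ²_df/df)
(600-point trapezoid over W's 1e−13…1−1e−13 quantile range; agreement
with scipy in the trusted region is ~1e−7 or better). Numerator and
denominator of q_O always come from the *same* evaluator so the ratio
stays monotone in θ across the handover — the property root bracketing
relies on.

A genuine feature of the t backend, inherited from the heavy t tails: as
θ → −∞, q_O converges to the positive constant (t_crit/t_obs)^df rather
than 0. This does not affect estimation (the constant is far below any
inversion target for originals that are more than negligibly significant).

## Estimation, CI and test

The point estimate solves x(θ) = 1; CI bounds solve x(θ) at the
Irwin–Hall α/2 and 1−α/2 quantiles. Because x increases in θ, the *lower*
bound pairs with the *lower* quantile. Root finding uses Brent's method on
an initial bracket of ±6 on the analysis scale (doubled up to four times),
θ-tolerance 1e−12, followed by a residual check: at the estimate the
residual |x(θ̂)−1| is at machine-precision level; at CI bounds it is
limited to ~1e−7 by deep-tail evaluation noise, and the acceptance
threshold is 1e−6. If the bracket cannot be established the fit raises a
`ConvergenceError` with diagnostics. This failure is reachable: when the
original's p value lies within ~1e−4 of its threshold, the conditional
probability becomes insensitive to θ and the lower confidence bound
genuinely diverges — the known pathology of conditional-probability
estimators that motivates the two variants:

- **hybrid⁰**: if x(0) > 1 (the combined evidence points the wrong way)
  the point estimate is set to 0; CI and p are inherited from hybrid.
- **hybridᴿ**: if the original's two-tailed p (computed under the pair's
  backend) is below α/2 the full hybrid result is returned; otherwise the
  replication-only result. A tie at exactly α/2 goes to the replication
  branch (the rule is stated with strict inequalities; the boundary has
  probability zero and the replication branch is the conservative side).

Fixed-effect pooling uses inverse-variance weights w_i = 1/σ̂_i² with a
normal reference; replication-only is the single-study normal-theory
result. When the predicted direction is negative, both effects are
mirrored before analysis and all results mirrored back.

## Analytic performance evaluation

The evaluation module reproduces estimator behavior deterministically on
the Fisher-z/normal backend. For a condition (ρ, N_O, N_R), the marginal
of the significant original is discretized into grid_n percentiles
P_i = 1 − π + iπ/(grid_n+1) — equally spaced through the surviving tail
mass π, the power of the one-tailed selection test at α = .025 — and the
replication marginal into P_i = i/(grid_n+1). Every method is applied to
all grid_n² equally weighted combinations.

Choices made here:

- grid_n defaults to 1000 (reference resolution); results are stable to
  <.003 under grid halving. Tests use 300 where point estimates are
  involved, with tolerances widened to ±.01.
- The hybrid-family point estimates over the grid are found by vectorized
  bisection on [−6, 6] with a fixed 60 iterations (interval 12/2⁶⁰), for
  exact run-to-run reproducibility; a root escaping the bracket raises
  with cell indices.
- Error rates and coverage need no root finding: by monotonicity,
  θ ∈ CI ⟺ x(θ) lies between the Irwin–Hall quantiles, and the one-tailed
  test rejects ⟺ x(0) ≤ Q(.025). Coverage/Type-I checks therefore run at
  full 1000-point resolution even in the test suite.
- All six summaries (mean, median, SD, RMSE, coverage, rejection rate)
  are computed on the correlation scale after tanh back-transform;
  coverage is decided on the z scale, equivalent under the monotone map.
- Rejection is one-tailed at α = .025 for *every* method including
  fixed-effect pooling, so Type I errors are comparable across methods
  (the replication's is exactly .025 by the percentile construction).

On this grid the reference behavior reproduces: fixed-effect mean
estimate ≈ .215 at ρ = 0, N = 31/31; hybrid mean ≈ −.013 with median
exactly ρ; hybrid/hybrid⁰/replication Type I = .025; hybridᴿ = .037;
hybrid coverage = .950.

## Monte-Carlo simulator

`simulate_pairs` draws originals from N(atanh ρ, 1/(N_O−3)) and rejects
until significant (geometrically expanding batches bound the loop), and
replications unconditionally; it is seeded and reproducible. It emulates
exactly the selection model above — one common fixed effect, normal
sampling on the Fisher-z scale, hard one-tailed truncation of the
original. It does *not* emulate heterogeneity between original and
replication, p-hacking or other questionable research practices, soft
(probabilistic) publication selection, or non-normal effect measures;
passing tests therefore validate the method under its own assumptions,
not robustness to their violation.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `alpha` | .05 | two-tailed selection level of the original; selection is one-tailed at α/2 |
| `ci_level` | .95 | confidence level of all intervals |
| `backend` | auto | `nct` for mean designs, `normal` for correlations |
| `grid_n` | 1000 | percentile-grid resolution per margin in the evaluation module |
| `alpha_one_tailed` | .025 | selection threshold and test level on the analytic grid |

## Known limitations

- Exactly one original and one replication; no extension to k studies.
- The hybrid CI (and for near-threshold originals the estimate itself)
  can be extremely wide or divergent when the original is only marginally
  significant — by construction, not by numerical accident.
- The reference worked example's published CI lower bound (−1.109) is not
  reproduced: accurate noncentral-t computation, cross-checked against
  direct quadrature of the t density, gives −1.222. Tail ratios of order
  1e−12/1e−12 are beyond the absolute accuracy of the legacy AS-243
  noncentral-t routine that desktop tools of the period relied on, and
  recomputing with that routine shows wild non-monotonicity exactly in
  that region. The upper bound (0.428) and all other reference values
  reproduce.
- Observed power computed from an estimated effect is imprecise at the
  sample sizes where it is most tempting to use; it is an index of the
  original study's design quality, not evidence about the effect.
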