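# hybridmeta

Meta-analysis of **one statistically significant original study and one
replication**, correcting the original for its selection on significance.

A published original study is usually in the literature *because* it was
significant. Conditional on significance, its expected effect size exceeds
the true effect — the winner's curse — irrespective of publication bias, so
naively pooling it with a replication (fixed-effect meta-analysis)
overestimates. `hybridmeta` implements the *hybrid* family of estimators,
which combine the two studies on the p-uniform principle: probabilities
computed at the true effect are uniformly distributed, *provided* the
original's probability is computed conditional on its selection.

## The statistic

For a hypothesized common effect θ, the package computes

- q_O = P(y ≥ y_O; θ) / P(y ≥ y_O^CV; θ) — the original's upper-tail
  probability conditional on exceeding its significance threshold y_O^CV
  (a truncated-distribution probability-integral transform), and
- q_R = P(y ≥ y_R; θ) — the replication's plain upper-tail probability.

At the true θ each is uniform on (0, 1), so x = q_O + q_R follows the
two-term Irwin–Hall distribution with CDF F(x) = x²/2 on [0, 1],
−x²/2 + 2x − 1 on [1, 2]. This yields:

- **test**: one-tailed p = F(x | θ=0), two-tailed p = G(x | θ=0) with
  G(x) = 2·min(F, 1−F);
- **estimate**: the θ at which x = 1 (the Irwin–Hall median), found by
  bracketed root finding — x is monotone in θ;
- **confidence interval**: test inversion, solving x(θ) at the Irwin–Hall
  2.5th and 97.5th percentiles (0.224 and 1.776).

Two variants guard against the strongly negative estimates that occur when
the original's p value sits near its threshold: **hybrid⁰** truncates the
estimate at 0 when x(0) > 1, and **hybridᴿ** discards the original entirely
(returning the replication result) when the original's two-tailed p ≥ .025.
Classical fixed-effect pooling and replication-only estimation are included
for comparison, along with sample-size-based guidelines for choosing among
the methods and an observed-power utility.

Supported designs: two-group and one-group mean differences (analyzed as
Hedges' g with exact noncentral-t probabilities) and correlations (analyzed
as Fisher z with normal probabilities, reported back as r).

## Worked example

An original study reports t(78) = 2.211 (n = 40 per group, p = .03); a
replication twice its size reports t(158) = 1.040 (p = .30):

```python
import hybridmeta as hm

pair = hm.StudyPair(original=hm.g_from_t(2.211, 40, 40),
                    replication=hm.g_from_t(1.040, 80, 80))
for name, res in hm.analyze_pair(pair).items():
    print(f"{name:13s} {res.estimate: .3f}  "
          f"95% CI ({res.ci_low: .3f}, {res.ci_high: .3f})  "
          f"p = {res.p_two_tailed:.3f}")
```

prints

```
fixed_effect   0.270  95% CI ( 0.016,  0.525)  p = 0.037
replication    0.164  95% CI (-0.147,  0.474)  p = 0.301
hybrid         0.103  95% CI (-1.222,  0.428)  p = 0.561
hybrid0        0.103  95% CI (-1.222,  0.428)  p = 0.561
hybridR        0.164  95% CI (-0.147,  0.474)  p = 0.301
```

Fixed-effect pooling calls the effect significant (g = 0.270, p = .037).
Undoing the original's selection reverses the verdict: the hybrid estimate
is small (g = 0.103) and nowhere near significant (p = .561) — at θ = 0 the
original's conditional probability is q_O = .015/.025 = 0.6 and the
replication contributes q_R = .15, giving x = 0.75. Because the original is
only marginally significant (p = .03 > .025), hybridᴿ drops it and returns
the replication result. See `examples/` for this and three more narrative
scripts (correlations, analytic performance, Monte-Carlo recovery).

There is also a thin CLI: `hybridmeta analyze`, `hybridmeta evaluate`,
`hybridmeta simulate` (see `--help`).

## Evaluating the estimators analytically

`hybridmeta.evaluate_condition` reproduces the estimators' sampling
behavior without simulation: the joint density of (significant original,
replication) is discretized into an equally weighted percentile grid
(truncated percentiles P_i = 1 − π + iπ/(n+1) for the original, plain
i/(n+1) for the replication, on the Fisher-z scale), every method is
applied to each of the n × n combinations, and bias, median, SD, RMSE,
coverage and rejection rate are accumulated on the correlation scale. At
ρ = 0 with n = 31 per study this shows fixed-effect pooling averaging
r ≈ 0.215 with a one-third Type I error rate, while the hybrid stays
unbiased in median with Type I error at the nominal .025 and 95% coverage.

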