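import dataclasses
import math

import numpy as np
import pytest
from scipy import stats

import hybridmeta as hm


def _dense_grid_root(pair, target, lo=-2.5, hi=1.5):
    """Brute-force oracle: theta minimizing |x(theta) - target|, by a
    coarse scan refined to a step of 1e-4."""
    for step in (0.01, 1e-4):
        thetas = np.arange(lo, hi, step)
        xs = np.array([hm.x_statistic(pair, float(t)).x for t in thetas])
        best = float(thetas[np.argmin(np.abs(xs - target))])
        lo, hi = best - 2 * step, best + 2 * step
    return best


class TestFixedEffect:
    def test_demo_pair_pooled_estimate(self, demo_pair):
        res = hm.fixed_effect_meta([demo_pair.original, demo_pair.replication])
        assert res.estimate == pytest.approx(0.270, abs=1e-3)
        assert res.ci_low == pytest.approx(0.016, abs=1e-3)
        assert res.ci_high == pytest.approx(0.525, abs=1e-3)
        assert res.p_two_tailed == pytest.approx(0.0375, abs=3e-4)

    def test_equal_variances_give_arithmetic_mean(self):
        a = hm.z_from_r(0.2, 50)
        b = hm.z_from_r(0.5, 50)
        res = hm.fixed_effect_meta([a, b])
        assert res.estimate == pytest.approx((a.y + b.y) / 2, rel=1e-14)

    def test_single_study_passthrough(self):
        a = hm.z_from_r(0.3, 60)
        res = hm.fixed_effect_meta([a])
        assert res.estimate == a.y
        assert res.variance == pytest.approx(a.variance, rel=1e-14)

    def test_k_identical_studies_shrink_variance(self):
        a = hm.z_from_r(0.3, 60)
        for k in (2, 5):
            res = hm.fixed_effect_meta([a] * k)
            assert res.variance == pytest.approx(a.variance / k, rel=1e-12)

    def test_mixed_metrics_rejected(self):
        with pytest.raises(ValueError):
            hm.fixed_effect_meta([hm.z_from_r(0.3, 60), hm.g_from_t(2.5, 40, 40)])


class TestReplicationOnly:
    def test_demo_pair(self, demo_pair):
        res = hm.replication_only(demo_pair.replication)
        assert res.estimate == pytest.approx(0.164, abs=5e-4)
        assert res.ci_low == pytest.approx(-0.147, abs=1e-3)
        assert res.ci_high == pytest.approx(0.474, abs=1e-3)
        assert res.p_two_tailed == pytest.approx(0.30, abs=5e-3)

    def test_null_effect_gives_p_one(self):
        est = hm.EffectEstimate(metric=hm.Metric.FISHER_Z, y=0.0, variance=0.02)
        assert hm.replication_only(est).p_two_tailed == 1.0

    def test_ci_width_closed_form(self):
        est = hm.z_from_r(0.25, 80)
        res = hm.replication_only(est, ci_level=0.95)
        assert res.ci_high - res.ci_low == pytest.approx(
            2 * 1.959964 * est.se, abs=1e-6)


class TestHybrid:
    def test_demo_pair_estimate_and_p(self, demo_pair):
        res = hm.hybrid_fit(demo_pair)
        assert res.estimate == pytest.approx(0.103, abs=5e-3)
        assert res.p_two_tailed == pytest.approx(0.5614, abs=1e-3)
        assert res.ci_high == pytest.approx(0.428, abs=2e-3)
        # lower bound from accurate noncentral-t tails (quadrature-verified)
        assert res.ci_low == pytest.approx(-1.2218, abs=2e-3)
        assert res.statistic == pytest.approx(0.7493, abs=1e-3)

    def test_estimate_solves_x_equals_one(self, demo_pair, correlation_pair,
                                          simulated_pairs):
        for pair in [demo_pair, correlation_pair] + simulated_pairs[:4]:
            est = hm.hybrid_fit(pair).estimate
            assert abs(hm.x_statistic(pair, est).x - 1.0) < 1e-8

    def test_root_matches_dense_grid_oracle(self, demo_pair, correlation_pair):
        for pair in (demo_pair, correlation_pair):
            res = hm.hybrid_fit(pair)
            assert abs(res.estimate - _dense_grid_root(pair, 1.0)) < 1e-3
            assert abs(res.ci_high -
                       _dense_grid_root(pair, hm.irwin_hall_quantile(0.975))) < 1e-3

    def test_ci_and_test_coherent(self, simulated_pairs):
        # theta = 0 excluded from the 95% CI exactly when two-tailed p < .05
        for pair in simulated_pairs:
            res = hm.hybrid_fit(pair)
            outside = res.ci_low > 0.0 or res.ci_high < 0.0
            assert outside == (res.p_two_tailed < 0.05)

    def test_mirrored_pair_mirrors_results(self):
        pos = hm.StudyPair(original=hm.z_from_r(0.45, 55),
                           replication=hm.z_from_r(0.10, 96),
                           backend=hm.Backend.NORMAL)
        neg = hm.StudyPair(original=hm.z_from_r(-0.45, 55),
                           replication=hm.z_from_r(-0.10, 96),
                           rule=hm.SignificanceRule(direction="negative"),
                           backend=hm.Backend.NORMAL)
        rp, rn = hm.hybrid_fit(pos), hm.hybrid_fit(neg)
        assert rn.estimate == pytest.approx(-rp.estimate, abs=1e-9)
        assert rn.ci_low == pytest.approx(-rp.ci_high, abs=1e-9)
        assert rn.ci_high == pytest.approx(-rp.ci_low, abs=1e-9)
        assert rn.p_two_tailed == pytest.approx(rp.p_two_tailed, abs=1e-12)


class TestHybridVariants:
    def test_hybrid0_keeps_hybrid_when_x0_below_one(self, demo_pair):
        base = hm.hybrid_fit(demo_pair)
        res = hm.hybrid0_fit(demo_pair)
        assert res.estimate == base.estimate
        assert (res.ci_low, res.ci_high, res.p_two_tailed) == \
            (base.ci_low, base.ci_high, base.p_two_tailed)
        assert res.branch_taken == "hybrid"

    def test_hybrid0_truncates_negative_evidence_to_zero(self):
        # just-significant original, replication pointing the other way
        pair = hm.StudyPair(original=hm.z_from_r(0.30, 48),
                            replication=hm.z_from_r(-0.25, 96),
                            backend=hm.Backend.NORMAL)
        assert hm.x_statistic(pair, 0.0).x > 1.0
        res = hm.hybrid0_fit(pair)
        assert res.estimate == 0.0
        assert res.branch_taken == "zero"
        base = hm.hybrid_fit(pair)
        assert base.estimate < 0.0
        assert res.p_two_tailed == base.p_two_tailed

    def test_hybrid0_estimate_never_negative(self, simulated_pairs):
        for pair in simulated_pairs:
            assert hm.hybrid0_fit(pair).estimate >= 0.0

    def test_hybridR_takes_replication_branch_for_marginal_original(self, demo_pair):
        # original two-tailed p = .03 exceeds .025
        res = hm.hybridR_fit(demo_pair)
        repl = hm.replication_only(demo_pair.replication)
        assert res.branch_taken == "replication"
        assert res.estimate == repl.estimate
        assert res.p_two_tailed == repl.p_two_tailed

    def test_hybridR_keeps_hybrid_for_convincing_original(self):
        pair = hm.StudyPair(original=hm.g_from_t(2.7, 40, 40),
                            replication=hm.g_from_t(1.0, 80, 80))
        assert pair.original_p_two_tailed() < 0.025
        res = hm.hybridR_fit(pair)
        base = hm.hybrid_fit(pair)
        assert res.branch_taken == "hybrid"
        for f in ("estimate", "ci_low", "ci_high", "statistic", "p_two_tailed"):
            assert getattr(res, f) == getattr(base, f)

    def test_hybridR_branch_equivalence(self, simulated_pairs):
        # hybrid-R is bitwise one of its two parents, decided by p_O vs .025
        numeric = ("estimate", "ci_low", "ci_high", "statistic",
                   "p_two_tailed", "p_one_tailed")
        for pair in simulated_pairs:
            res = hm.hybridR_fit(pair)
            if pair.original_p_two_tailed() < 0.025:
                ref = hm.hybrid_fit(pair)
            else:
                ref = hm.replication_only(pair.replication)
            for f in numeric:
                assert getattr(res, f) == getattr(ref, f)


class TestOneSampleDesign:
    def test_hybrid_pipeline_on_one_sample_t(self):
        pair = hm.StudyPair(original=hm.one_sample_g_from_t(2.5, 30),
                            replication=hm.one_sample_g_from_t(1.0, 50))
        assert pair.backend is hm.Backend.NCT
        res = hm.hybrid_fit(pair)
        assert res.ci_low < res.estimate < res.ci_high
        assert abs(hm.x_statistic(pair, res.estimate).x - 1.0) < 1e-8
        # corrected estimate sits below the naive pooled estimate
        fe = hm.fixed_effect_meta([pair.original, pair.replication])
        assert res.estimate < fe.estimate


class TestForcedNonSignificantPair:
    def test_hybrid_fit_cannot_converge(self):
        pair = hm.StudyPair(original=hm.z_from_r(0.1, 31),
                            replication=hm.z_from_r(0.1, 31),
                            backend=hm.Backend.NORMAL, force=True)
        with pytest.raises(hm.ConvergenceError):
            hm.hybrid_fit(pair)

    def test_analyze_pair_degrades_gracefully(self):
        pair = hm.StudyPair(original=hm.z_from_r(0.1, 31),
                            replication=hm.z_from_r(0.1, 31),
                            backend=hm.Backend.NORMAL, force=True)
        out = hm.analyze_pair(pair)
        assert math.isnan(out["hybrid"].estimate)
        assert out["hybrid"].branch_taken == "failed"
        assert 0 <= out["hybrid"].p_two_tailed <= 1
        assert not math.isnan(out["fixed_effect"].estimate)
        assert not math.isnan(out["replication"].estimate)


class TestAdvisor:
    @pytest.mark.parametrize(
        "N_O, N_R, expectation, method, guideline",
        [
            (80, 160, "uncertain", hm.Method.REPLICATION, "1a"),
            (96, 31, "uncertain", hm.Method.HYBRID_R, "1b"),
            (50, 50, "uncertain", hm.Method.HYBRID_R, "1b"),  # tie -> 1b
            (31, 96, "zero_or_small", hm.Method.HYBRID_R, "2"),
            (40, 40, "medium_or_large", hm.Method.FIXED_EFFECT, "3"),
            (31, 783, "medium_or_large", hm.Method.FIXED_EFFECT, "3"),
        ],
    )
    def test_guideline_truth_table(self, N_O, N_R, expectation, method, guideline):
        advice = hm.advise_method(N_O, N_R, expectation)
        assert advice.recommended is method
        assert advice.guideline_id == guideline

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            hm.advise_method(0, 10, "uncertain")
        with pytest.raises(ValueError):
            hm.advise_method(10, 10, "huge")


class TestObservedPower:
    def test_small_effect_low_power(self):
        assert hm.observed_power(0.164, 40, 40, 0.05) == pytest.approx(0.18, abs=1e-2)

    def test_size_under_the_null(self):
        assert hm.observed_power(0.0, 30, 50, 0.05) == pytest.approx(0.05, abs=1e-10)

    def test_power_tends_to_one(self):
        assert hm.observed_power(5.0, 40, 40, 0.05) > 0.999999
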