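"""Condition-effect ANOVA (with paired-t and statsmodels oracles), admixture
curve fitting and flip-threshold inversion."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from scoreval import (
    DataError,
    DecisionPolicy,
    PreTestGroup,
    fit_admixture_curve,
    invert_threshold,
)
from scoreval.interference import test_condition_effect as condition_effect_anova
from scoreval.interference import NO_CALL_CHANGE, _fourpl
from scoreval.synthetic import (
    AdmixtureDesign,
    generate_admixture_series,
    generate_condition_scores,
)


class TestConditionEffect:
    def test_zero_noise_null_gives_f_zero(self):
        f = generate_condition_scores([0.0, 1.0, 2.0], ["a", "b"], [0, 0],
                                      sigma_residual=0.0, replicates=2, seed=0)
        res = condition_effect_anova(f)
        assert res.f_statistic == pytest.approx(0.0, abs=1e-20)

    def test_two_level_f_equals_squared_paired_t(self):
        # with one replicate per cell the blocked ANOVA F is exactly the
        # square of the paired t statistic
        rng = np.random.default_rng(7)
        n = 12
        a = rng.normal(0, 1, n)
        b = a + 0.3 + rng.normal(0, 0.5, n)
        rows = []
        for i in range(n):
            rows.append({"sample_id": f"s{i:02d}", "condition": "lvl_a",
                         "replicate_id": "1", "score": a[i]})
            rows.append({"sample_id": f"s{i:02d}", "condition": "lvl_b",
                         "replicate_id": "1", "score": b[i]})
        res = condition_effect_anova(pd.DataFrame(rows))
        t, p = stats.ttest_rel(a, b)
        assert res.f_statistic == pytest.approx(t**2, rel=1e-10)
        assert res.p_value == pytest.approx(p, rel=1e-10)
        assert res.df_denominator == n - 1

    def test_matches_statsmodels_anova(self):
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        f = generate_condition_scores(
            np.linspace(-1, 1, 5), ["10", "15", "20"], [-0.2, 0.0, 0.1],
            sigma_residual=0.15, replicates=3, seed=8,
        )
        res = condition_effect_anova(f)
        fit = smf.ols("score ~ C(sample_id) + C(condition)", data=f).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert res.f_statistic == pytest.approx(tab.loc["C(condition)", "F"], rel=1e-9)
        assert res.p_value == pytest.approx(tab.loc["C(condition)", "PR(>F)"], rel=1e-9)

    def test_level_effects_sum_to_zero_and_recover_shift(self):
        b = [-0.3, 0.0, 0.0]
        f = generate_condition_scores(np.zeros(80), ["x", "y", "z"], b,
                                      sigma_residual=0.1, replicates=2, seed=9)
        res = condition_effect_anova(f)
        vals = np.array(list(res.level_effects.values()))
        assert vals.sum() == pytest.approx(0.0, abs=1e-10)
        centred = np.array(b) - np.mean(b)
        keys = sorted(res.level_effects)
        assert res.level_effects[keys[0]] == pytest.approx(centred[0], abs=0.02)
        assert res.significant

    def test_significance_threshold_respected(self):
        f = generate_condition_scores(np.linspace(-1, 1, 4),
                                      ["a", "b"], [0.0, 0.0],
                                      sigma_residual=0.1, replicates=3, seed=10)
        res = condition_effect_anova(f, alpha=0.05)
        assert res.significant == (res.p_value < 0.05)

    def test_missing_cell_rejected(self):
        f = generate_condition_scores([0.0, 1.0], ["a", "b"], [0, 0], seed=11)
        f = f[~((f.sample_id == "sample_001") & (f.condition == "a"))]
        with pytest.raises(DataError, match="missing"):
            condition_effect_anova(f)


class TestCurveFit:
    def test_exact_line_reproduced_with_zero_residual(self):
        pts = [(p, np.array([2.0 * p - 1.0])) for p in (0, 0.2, 0.5, 0.8, 1.0)]
        curve = fit_admixture_curve(pts)
        grid = np.linspace(0, 1, 11)
        assert np.allclose(curve(grid), 2.0 * grid - 1.0, atol=1e-8)
        assert curve.fit_residual_sd == pytest.approx(0.0, abs=1e-8)

    def test_logistic_points_recovered_to_1e6(self):
        truth = (-1.0, 1.5, 6.0, 0.45)
        props = np.array([0.0, 0.05, 0.1, 0.2, 0.5, 0.75, 1.0])
        pts = [(p, np.array([_fourpl(p, *truth)])) for p in props]
        curve = fit_admixture_curve(pts)
        assert curve.family == "4pl"
        assert np.allclose(curve(props), _fourpl(props, *truth), atol=1e-6)

    def test_fitted_curve_nondecreasing_for_high_scoring_contaminant(self):
        d = AdmixtureDesign(base_score=-1.0, contaminant_score=1.6,
                            replicate_noise_sd=0.05, seed=12)
        curve = fit_admixture_curve(generate_admixture_series(d))
        grid = np.linspace(0, 1, 201)
        assert np.all(np.diff(curve(grid)) >= -1e-9)

    def test_sparse_design_falls_back_to_interpolation(self):
        pts = [(0.0, np.array([0.0])), (0.5, np.array([0.4])), (1.0, np.array([1.0]))]
        curve = fit_admixture_curve(pts)
        assert curve.family == "interp"
        assert curve(0.25) == pytest.approx(0.2)

    def test_non_monotone_data_warns(self):
        pts = [(0.0, np.array([0.0])), (0.3, np.array([1.0])),
               (0.6, np.array([-1.0])), (1.0, np.array([2.0]))]
        with pytest.warns(UserWarning, match="non-monotone"):
            fit_admixture_curve(pts)


class TestInvertThreshold:
    def test_linear_blend_closed_form(self, policy):
        s0, s1 = -0.8, 1.6
        pts = [(p, np.array([s0 + (s1 - s0) * p])) for p in (0, 0.25, 0.5, 0.75, 1.0)]
        curve = fit_admixture_curve(pts)
        rep = invert_threshold(curve, policy, PreTestGroup.INTERMEDIATE)
        by_boundary = {t.boundary: t for t in rep.thresholds}
        for boundary, cut in (("down", policy.intermediate_down_cut),
                              ("up", policy.intermediate_up_cut)):
            expected = (cut - s0) / (s1 - s0)
            assert by_boundary[boundary].threshold_proportion == pytest.approx(
                expected, abs=1e-6
            )

    def test_flat_curve_reports_no_call_change(self, policy):
        pts = [(p, np.array([0.0])) for p in (0, 0.3, 0.6, 1.0)]
        curve = fit_admixture_curve(pts)
        rep = invert_threshold(curve, policy, PreTestGroup.INTERMEDIATE)
        assert all(t.threshold_proportion is None for t in rep.thresholds)
        assert all(t.describe() == NO_CALL_CHANGE for t in rep.thresholds)

    def test_high_pretest_with_subthreshold_contaminant_never_flips(self, policy):
        # base and contaminant both inside the high category (below the
        # very-high cut): mixing can never alter the call
        d = AdmixtureDesign(base_score=0.5, contaminant_score=1.1,
                            replicate_noise_sd=0.0, pre_test=PreTestGroup.HIGH, seed=13)
        curve = fit_admixture_curve(generate_admixture_series(d))
        rep = invert_threshold(curve, policy, PreTestGroup.HIGH)
        assert [t.describe() for t in rep.thresholds] == [NO_CALL_CHANGE]

    def test_antitone_in_boundary_distance(self):
        s0, s1 = -1.0, 2.0
        pts = [(p, np.array([s0 + (s1 - s0) * p])) for p in (0, 0.25, 0.5, 0.75, 1.0)]
        curve = fit_admixture_curve(pts)
        thresholds = []
        for up_cut in (0.3, 0.8, 1.3):
            pol = DecisionPolicy(intermediate_up_cut=up_cut)
            rep = invert_threshold(curve, pol, PreTestGroup.INTERMEDIATE)
            t = {x.boundary: x for x in rep.thresholds}["up"]
            thresholds.append(t.threshold_proportion)
        assert thresholds == sorted(thresholds)

    def test_steeper_contaminant_gives_smaller_threshold(self, policy):
        base = -0.8
        res = {}
        for name, contaminant in (("weak", 1.2), ("strong", 2.4)):
            pts = [(p, np.array([base + (contaminant - base) * p]))
                   for p in (0, 0.25, 0.5, 0.75, 1.0)]
            rep = invert_threshold(fit_admixture_curve(pts), policy,
                                   PreTestGroup.INTERMEDIATE)
            res[name] = {t.boundary: t.threshold_proportion for t in rep.thresholds}
        assert res["strong"]["up"] <= res["weak"]["up"]
        assert res["strong"]["down"] <= res["weak"]["down"]

    def test_lower_scoring_contaminant_needs_larger_proportion(self, policy):
        # qualitative two-contaminant structure of the blood study
        thresholds = {}
        for name, cscore in (("low_blood", 0.8), ("high_blood", 1.7)):
            d = AdmixtureDesign(base_score=-1.0, contaminant_score=cscore,
                                replicate_noise_sd=0.0,
                                pre_test=PreTestGroup.LOW, seed=14)
            curve = fit_admixture_curve(generate_admixture_series(d))
            rep = invert_threshold(curve, policy, PreTestGroup.LOW)
            thresholds[name] = rep.thresholds[0].threshold_proportion
        assert thresholds["low_blood"] >= thresholds["high_blood"]

    def test_unfitted_curve_rejected(self, policy):
        with pytest.raises(DataError):
            invert_threshold(None, policy, PreTestGroup.LOW)
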