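"""Variance decomposition against a brute-force oracle, bootstrap mechanics,
inter-lab SD and concordance."""

import numpy as np
import pandas as pd
import pytest

from scoreval import (
    DataError,
    bootstrap_ci,
    compose_sd,
    concordance,
    decompose_variance,
    fraction_of_range,
    interlab_sd,
    round_percent,
)
from scoreval.synthetic import ReproDesign, generate_interlab_scores, generate_reproducibility_scores
from scoreval.varcomp import _components_from_array


def brute_force_components(y):
    """Independent oracle: explicit loops over the ANOVA sums of squares."""
    a, b, r = y.shape
    grand = y.mean()
    ss_run = 0.0
    for j in range(b):
        ss_run += a * r * (y[:, j, :].mean() - grand) ** 2
    ss_int, ss_within = 0.0, 0.0
    for i in range(a):
        for j in range(b):
            cell = y[i, j, :].mean()
            ss_int += r * (cell - y[i].mean() - y[:, j, :].mean() + grand) ** 2
            for k in range(r):
                ss_within += (y[i, j, k] - cell) ** 2
    ms_w = ss_within / (a * b * (r - 1))
    ms_int = ss_int / ((a - 1) * (b - 1))
    ms_run = ss_run / (b - 1)
    v_res = ms_w
    v_int = max((ms_int - ms_w) / r, 0.0)
    v_run = max((ms_run - ms_int) / (r * a), 0.0)
    return v_run, v_int, v_res


def frame_from_array(y):
    a, b, r = y.shape
    idx = pd.MultiIndex.from_product(
        [[f"s{i:02d}" for i in range(a)], [f"run{j}" for j in range(b)],
         [f"rep{k}" for k in range(r)]],
        names=["sample_id", "run_id", "replicate_id"],
    ).to_frame(index=False)
    idx["lab_id"] = "lab_A"
    idx["condition"] = "nominal"
    idx["score"] = y.ravel()
    return idx


class TestDecomposeVariance:
    def test_reported_sds_compose_orthogonally(self):
        # the three headline SDs satisfy total^2 = intra^2 + inter^2
        assert round(compose_sd(0.117, 0.136), 3) == 0.179

    def test_constant_table_gives_zero_components(self):
        y = np.full((4, 3, 2), 1.23)
        vd = decompose_variance(frame_from_array(y))
        assert vd.sigma_intra == pytest.approx(0.0, abs=1e-8)
        assert vd.sigma_run == pytest.approx(0.0, abs=1e-7)
        assert vd.sigma_interaction == pytest.approx(0.0, abs=1e-7)
        assert vd.sigma_total == pytest.approx(0.0, abs=1e-7)

    @pytest.mark.parametrize("shape", [(3, 2, 2), (5, 3, 2), (10, 4, 3), (7, 2, 5)])
    def test_matches_brute_force_oracle(self, shape):
        rng = np.random.default_rng(sum(shape))
        y = rng.normal(0, 1, shape) + rng.normal(0, 0.5, (shape[0], 1, 1))
        vd = decompose_variance(frame_from_array(y))
        v_run, v_int, v_res = brute_force_components(y)
        assert vd.sigma_run**2 == pytest.approx(v_run, abs=1e-10)
        assert vd.sigma_interaction**2 == pytest.approx(v_int, abs=1e-10)
        assert vd.sigma_intra**2 == pytest.approx(v_res, abs=1e-10)

    def test_pythagorean_identity_exact(self, repro_design):
        vd = decompose_variance(generate_reproducibility_scores(repro_design))
        assert vd.sigma_total**2 == pytest.approx(
            vd.sigma_intra**2 + vd.sigma_inter**2, rel=1e-12
        )
        assert vd.sigma_inter**2 == pytest.approx(
            vd.sigma_run**2 + vd.sigma_interaction**2, rel=1e-12
        )

    def test_variance_estimates_unbiased(self):
        # mean of the (untruncated) variance-scale estimates over many
        # datasets approaches the generating parameters
        rng = np.random.default_rng(21)
        a, b, r, n = 30, 3, 3, 400
        s_run, s_int, s_res = 0.10, 0.05, 0.12
        y = (rng.normal(0, s_run, (n, 1, b, 1))
             + rng.normal(0, s_int, (n, a, b, 1))
             + rng.normal(0, s_res, (n, a, b, r)))
        comp = _components_from_array(y)
        for key, true in [("v_res", s_res**2), ("v_int", s_int**2), ("v_run", s_run**2)]:
            est = comp[key].mean()
            se = comp[key].std(ddof=1) / np.sqrt(n)
            # truncation at zero biases v_run/v_int upward slightly; allow 4 SE
            assert abs(est - true) < 4 * se + 1e-4

    def test_high_df_components_recovered_on_one_large_table(self):
        d = ReproDesign(n_samples=200, n_controls=0, sigma_run=0.10,
                        sigma_interaction=0.05, sigma_residual=0.12, seed=22)
        vd = decompose_variance(generate_reproducibility_scores(d))
        assert vd.sigma_intra == pytest.approx(0.12, rel=0.05)
        assert vd.sigma_interaction == pytest.approx(0.05, rel=0.15)

    def test_negative_estimates_truncated_and_flagged(self):
        # no interaction, tiny interaction MS relative to within MS happens
        # often at small designs; scan seeds deterministically for one
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = rng.normal(0, 1.0, (3, 2, 2))
            vd = decompose_variance(frame_from_array(y))
            if vd.truncated:
                assert set(vd.truncated) <= {"run", "interaction"}
                assert vd.sigma_run >= 0 and vd.sigma_interaction >= 0
                return
        pytest.fail("no truncation observed over 30 seeds")

    def test_unbalanced_table_rejected(self):
        y = np.zeros((3, 2, 2))
        f = frame_from_array(y).iloc[:-1]  # drop one replicate
        with pytest.raises(DataError, match="unbalanced"):
            decompose_variance(f)

    def test_single_replicate_rejected(self):
        f = frame_from_array(np.zeros((3, 2, 1)))
        with pytest.raises(DataError, match="replication"):
            decompose_variance(f)

    def test_missing_cell_rejected(self):
        f = frame_from_array(np.zeros((3, 2, 2)))
        f = f[~((f.sample_id == "s00") & (f.run_id == "run1"))]
        with pytest.raises(DataError, match="missing"):
            decompose_variance(f)


class TestBootstrap:
    def test_zero_residual_table_gives_zero_width_ci(self):
        # cell means vary, within-cell residuals are all zero
        y = np.repeat(np.arange(12.0).reshape(3, 2, 2).mean(-1)[..., None], 2, axis=-1)
        ci = bootstrap_ci(frame_from_array(y), "varcomp", n_boot=200, seed=0)
        assert ci["intra"] == (0.0, 0.0)

    def test_percentile_interval_matches_quantiles(self):
        from scoreval.varcomp import _percentile_interval

        rng = np.random.default_rng(1)
        draws = rng.normal(0, 1, 1000)
        lo, hi = _percentile_interval(draws, 0.95)
        # independent sort-and-index computation
        s = np.sort(draws)
        assert lo == pytest.approx(np.quantile(s, 0.025))
        assert hi == pytest.approx(np.quantile(s, 0.975))
        assert s[24] <= lo <= s[26] and s[973] <= hi <= s[975]

    def test_order_invariance(self, repro_design):
        f = generate_reproducibility_scores(repro_design)
        shuffled = f.sample(frac=1.0, random_state=99).reset_index(drop=True)
        a = bootstrap_ci(f, "varcomp", n_boot=150, seed=5)
        b = bootstrap_ci(shuffled, "varcomp", n_boot=150, seed=5)
        assert a == b

    def test_ci_brackets_point_estimate(self, repro_design):
        f = generate_reproducibility_scores(repro_design)
        vd = decompose_variance(f, n_boot=300, seed=3)
        for comp in ("intra", "inter", "total"):
            lo, hi = vd.ci[comp]
            assert lo <= vd.sigma(comp) <= hi

    def test_n_boot_floor(self, repro_design):
        f = generate_reproducibility_scores(repro_design)
        with pytest.raises(DataError):
            bootstrap_ci(f, "varcomp", n_boot=50)


class TestInterlab:
    def test_identical_duplicates_give_zero_sigma(self):
        d = ReproDesign(n_samples=5, n_controls=0, sigma_residual=0,
                        sigma_run=0, sigma_interaction=0, seed=1)
        f = generate_interlab_scores(d)
        assert interlab_sd(f).sigma == 0.0

    def test_three_sample_hand_computation(self):
        rows = []
        scores = {"s1": (1.0, 1.2), "s2": (0.0, 0.4), "s3": (-1.0, -1.0)}
        for sid, (sa, sb) in scores.items():
            rows.append({"sample_id": sid, "lab_id": "A", "run_id": "r",
                         "replicate_id": "1", "condition": "nominal", "score": sa})
            rows.append({"sample_id": sid, "lab_id": "B", "run_id": "r",
                         "replicate_id": "1", "condition": "nominal", "score": sb})
        f = pd.DataFrame(rows)
        # residuals are +/- half the within-pair difference; df = 6 - 3 = 3
        ss = (0.1**2 + 0.1**2) + (0.2**2 + 0.2**2) + 0.0
        expected = np.sqrt(ss / 3)
        assert interlab_sd(f).sigma == pytest.approx(expected)

    def test_pct_of_range_for_reported_interlab_sd(self):
        assert round_percent(fraction_of_range(0.169, 4.57)) == 3.7

    def test_sample_in_one_lab_rejected(self):
        d = ReproDesign(n_samples=4, n_controls=0, seed=2)
        f = generate_interlab_scores(d)
        f = f[~((f.sample_id == f.sample_id.iloc[0]) & (f.lab_id == "lab_B"))]
        with pytest.raises(DataError, match="only one lab"):
            interlab_sd(f)


class TestConcordance:
    def test_reported_discordance_fraction(self):
        calls_a = np.zeros(131, dtype=int)
        calls_b = np.zeros(131, dtype=int)
        calls_b[:13] = 1
        res = concordance(calls_a, calls_b)
        assert res.n_discordant == 13
        assert round_percent(100 * res.discordance_rate) == 9.9
        assert res.passed  # below the 15% acceptance bound

    def test_identical_calls_pass(self):
        res = concordance(["a", "b"], ["a", "b"], [0.0, 1.0], [0.1, 1.1])
        assert res.discordance_rate == 0.0 and res.passed

    def test_affine_scores_have_unit_r_squared(self):
        a = np.linspace(-1, 1, 20)
        res = concordance(np.zeros(20), np.zeros(20), a, 2 * a + 1)
        assert res.r_squared == pytest.approx(1.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(DataError):
            concordance([1, 2], [1])
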