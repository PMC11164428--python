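"""Tests for power analysis, MR harmonization/Wald ratio, CTCF, traces,
and group comparisons."""

import numpy as np
import pandas as pd
import pytest

from isletflux.downstream_stats import (
    PowerSpec,
    auc,
    classify_hi_lo,
    compare_groups,
    ctcf,
    fold_change,
    harmonize,
    normalize_trace,
    power_two_sample_t,
    ratio_trace,
    sample_size_two_sample_t,
    wald_ratio,
)


class TestPower:
    @pytest.mark.parametrize(
        "d,alpha,power,expected",
        [
            (1.5, 0.05, 0.80, 9),   # the tracing cohort size
            (1.5, 0.05, 0.90, 11),
            (10.0, 0.05, 0.80, 2),
        ],
    )
    def test_sample_sizes(self, d, alpha, power, expected):
        n = sample_size_two_sample_t(PowerSpec(d, alpha, power))
        assert n == expected
        # minimality: one fewer sample must fall short
        if expected > 2:
            assert power_two_sample_t(expected - 1, d, alpha) < power

    def test_monotonicity_lattice(self):
        """n is nonincreasing in d and alpha, nondecreasing in power."""
        for d in (0.8, 1.2, 1.5):
            for alpha in (0.01, 0.05):
                for target in (0.8, 0.9):
                    n = sample_size_two_sample_t(PowerSpec(d, alpha, target))
                    assert n >= sample_size_two_sample_t(
                        PowerSpec(d + 0.3, alpha, target)
                    )
                    assert n >= sample_size_two_sample_t(
                        PowerSpec(d, alpha * 2, target)
                    )
                    assert n <= sample_size_two_sample_t(
                        PowerSpec(d, alpha, target + 0.05)
                    )

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            PowerSpec(-1.0)
        with pytest.raises(ValueError):
            PowerSpec(1.5, alpha=1.5)


def mk_stats(rows):
    return pd.DataFrame(rows, columns=["snp", "ea", "oa", "beta", "se"])


class TestHarmonize:
    def test_flip_truth_table(self):
        exp = mk_stats([("rs1", "A", "G", 0.3, 0.05)])
        out = mk_stats([("rs1", "G", "A", -0.2, 0.04)])
        res = harmonize(exp, out)
        row = res.harmonized.iloc[0]
        assert (row["ea"], row["oa"]) == ("A", "G")
        assert row["beta_out"] == pytest.approx(0.2)

    def test_aligned_unchanged(self):
        exp = mk_stats([("rs1", "A", "G", 0.3, 0.05)])
        out = mk_stats([("rs1", "A", "G", 0.25, 0.04)])
        res = harmonize(exp, out)
        assert res.harmonized.iloc[0]["beta_out"] == pytest.approx(0.25)
        assert res.dropped.empty

    def test_palindromic_excluded(self):
        exp = mk_stats([("rs_at", "A", "T", 0.3, 0.05)])
        out = mk_stats([("rs_at", "A", "T", 0.2, 0.04)])
        res = harmonize(exp, out)
        assert res.harmonized.empty
        assert res.dropped.iloc[0]["reason"] == "palindromic"

    def test_incompatible_dropped(self):
        exp = mk_stats([("rs1", "A", "G", 0.3, 0.05)])
        out = mk_stats([("rs1", "A", "C", 0.2, 0.04)])
        res = harmonize(exp, out)
        assert res.harmonized.empty
        assert res.dropped.iloc[0]["reason"] == "incompatible_alleles"

    def test_idempotent(self):
        exp = mk_stats([("rs1", "A", "G", 0.3, 0.05),
                        ("rs2", "C", "T", -0.4, 0.06)])
        out = mk_stats([("rs1", "G", "A", -0.2, 0.04),
                        ("rs2", "C", "T", 0.1, 0.05)])
        once = harmonize(exp, out).harmonized
        again_out = once.rename(
            columns={"beta_out": "beta", "se_out": "se"}
        )[["snp", "ea", "oa", "beta", "se"]]
        twice = harmonize(exp, again_out).harmonized
        pd.testing.assert_frame_equal(once, twice)

    def test_recoding_invariance_of_wald_ratio(self):
        """Consistently re-coding outcome alleles must not change the MR
        estimate after harmonization."""
        exp = mk_stats([("rs1", "A", "G", 0.5, 0.05)])
        out1 = mk_stats([("rs1", "A", "G", 0.2, 0.1)])
        out2 = mk_stats([("rs1", "G", "A", -0.2, 0.1)])
        r1 = harmonize(exp, out1).harmonized.iloc[0]
        r2 = harmonize(exp, out2).harmonized.iloc[0]
        w1 = wald_ratio(r1["beta_exp"], r1["se_exp"], r1["beta_out"], r1["se_out"])
        w2 = wald_ratio(r2["beta_exp"], r2["se_exp"], r2["beta_out"], r2["se_out"])
        assert w1.estimate == pytest.approx(w2.estimate)


class TestWaldRatio:
    def test_ratio(self):
        assert wald_ratio(0.5, 0.05, 0.2, 0.1).estimate == pytest.approx(0.4)

    def test_unit_exposure_identity(self):
        assert wald_ratio(1.0, 0.05, -0.37, 0.1).estimate == pytest.approx(-0.37)

    def test_delta_se(self):
        assert wald_ratio(0.5, 0.01, 0.2, 0.1).se == pytest.approx(0.2)

    def test_zero_exposure_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.05, 0.2, 0.1)

    def test_delta_se_matches_monte_carlo(self):
        """When exposure SE << |beta_exp| the delta-method SE matches the
        simulation SD of the ratio within 5%."""
        rng = np.random.default_rng(20240411)
        b_exp, se_exp, b_out, se_out = 0.5, 0.005, 0.2, 0.1
        sims = rng.normal(b_out, se_out, 200_000) / rng.normal(
            b_exp, se_exp, 200_000
        )
        analytic = wald_ratio(b_exp, se_exp, b_out, se_out).se
        assert analytic == pytest.approx(sims.std(), rel=0.05)


class TestImaging:
    def test_ctcf_formula(self):
        assert ctcf(1e6, 200.0, 100.0) == pytest.approx(980_000.0)
        assert ctcf(1e6, 200.0, 0.0) == pytest.approx(1e6)
        assert ctcf(2e4, 200.0, 100.0) == pytest.approx(0.0)

    def test_ctcf_linear(self):
        rng = np.random.default_rng(0)
        i, a, b = rng.uniform(1, 10, 5), rng.uniform(1, 10, 5), rng.uniform(1, 10, 5)
        assert ctcf(2 * i, a, b) == pytest.approx(2 * ctcf(i, a, b) + a * b)
        assert ctcf(i, a, 2 * b) == pytest.approx(ctcf(i, a, b) - a * b)

    def test_hi_lo_threshold_strict(self):
        res = classify_hi_lo([9e4, 8e4, 7e4], threshold=8e4)
        assert list(res.labels) == ["Hi", "Lo", "Lo"]
        assert res.hi_proportion == pytest.approx(1 / 3)

    def test_hi_lo_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_hi_lo([])

    def test_proportion_ci_contains_truth_for_binomial_draws(self):
        rng = np.random.default_rng(20240411)
        values = np.where(rng.random(150) < 0.19, 1.5e5, 3e4)
        res = classify_hi_lo(values)
        lo, hi = res.proportion_ci()
        assert lo <= 0.19 <= hi


class TestTraces:
    def test_constant_trace_normalizes_to_one(self):
        out = normalize_trace(np.full(40, 3.7))
        assert out == pytest.approx(np.ones(40))

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        trace = rng.uniform(1, 2, 60)
        assert normalize_trace(2 * trace) == pytest.approx(normalize_trace(trace))

    def test_step_height(self):
        trace = np.concatenate([np.ones(21), np.full(30, 1.5)])
        out = normalize_trace(trace, baseline_window=(0, 20))
        assert out[-1] == pytest.approx(1.5)

    def test_min_mode(self):
        trace = np.array([4.0, 2.0, 6.0])
        assert normalize_trace(trace, mode="min") == pytest.approx([2, 1, 3])

    def test_ratio_trace(self):
        assert ratio_trace([4.0, 6.0], [2.0, 3.0]) == pytest.approx([2.0, 2.0])

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            normalize_trace(np.ones(10), baseline_window=(0, 20))

    def test_auc_zero_for_baseline_trace(self):
        assert auc(np.ones(50), (5, 45)) == pytest.approx(0.0)

    def test_auc_rectangle(self):
        assert auc(np.full(50, 2.0), (10, 30)) == pytest.approx(20.0)

    def test_auc_triangle(self):
        """Triangular bump of height h over 2w frames has area h*w."""
        h, w = 0.8, 10
        bump = 1.0 + h * (1 - np.abs(np.arange(-w, w + 1)) / w)
        trace = np.concatenate([np.ones(5), bump, np.ones(5)])
        assert auc(trace, (5, 5 + 2 * w)) == pytest.approx(h * w)

    def test_auc_time_units(self):
        assert auc(np.full(50, 2.0), (10, 30), frame_rate=0.33) == pytest.approx(
            20.0 / 0.33
        )

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            auc(np.ones(50), (30, 10))


class TestCompareGroups:
    @staticmethod
    def table(groups):
        rows = [
            {"group": g, "value": v} for g, values in groups.items() for v in values
        ]
        return pd.DataFrame(rows)

    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(5)
        x = rng.normal(0, 1, 12)
        t = self.table({"a": x, "b": x})
        res = compare_groups(t, "welch_t")
        assert res.omnibus["p"] == pytest.approx(1.0)

    def test_welch_matches_scipy(self):
        from scipy import stats as ss

        rng = np.random.default_rng(6)
        a, b = rng.normal(0, 1, 9), rng.normal(1, 2, 9)
        res = compare_groups(self.table({"a": a, "b": b}), "welch_t")
        stat, p = ss.ttest_ind(a, b, equal_var=False)
        assert res.omnibus["statistic"] == pytest.approx(stat)
        assert res.omnibus["p"] == pytest.approx(p)

    def test_one_way_sidak_adjustment(self):
        rng = np.random.default_rng(7)
        t = self.table(
            {"a": rng.normal(0, 1, 9), "b": rng.normal(0, 1, 9),
             "c": rng.normal(2, 1, 9)}
        )
        res = compare_groups(t, "one_way_anova_sidak")
        m = len(res.comparisons)
        assert m == 3
        expected = 1 - (1 - res.comparisons["p_raw"]) ** m
        assert res.comparisons["p_adjusted"].to_numpy() == pytest.approx(
            expected.to_numpy()
        )

    def test_two_way_needs_factor(self):
        t = self.table({"a": [1, 2, 3], "b": [4, 5, 6]})
        with pytest.raises(ValueError, match="factor"):
            compare_groups(t, "two_way_anova_sidak")

    def test_two_way_detects_group_effect(self):
        rng = np.random.default_rng(8)
        rows = []
        for species, shift in [("human", 1.0), ("mouse", 0.2)]:
            for channel in ("m+2", "m+3"):
                for v in rng.normal(shift, 0.1, 9):
                    rows.append({"group": species, "channel": channel, "value": v})
        res = compare_groups(
            pd.DataFrame(rows), "two_way_anova_sidak", factor="channel"
        )
        assert res.omnibus["p_group"] < 1e-6
        assert len(res.comparisons) == 2  # one pairwise test per channel
        assert (res.comparisons["p_adjusted"] < 1e-4).all()

    def test_kruskal_dunn_shapes(self):
        rng = np.random.default_rng(9)
        t = self.table(
            {"a": rng.normal(0, 1, 9), "b": rng.normal(0, 1, 9),
             "c": rng.normal(1.5, 1, 9)}
        )
        res = compare_groups(t, "kruskal_dunn")
        assert res.omnibus["test"] == "kruskal_wallis"
        assert len(res.comparisons) == 3
        assert (res.comparisons["p_adjusted"] >= res.comparisons["p_raw"] - 1e-12).all()

    def test_normality_screen_reported_not_applied(self):
        rng = np.random.default_rng(10)
        t = self.table({"a": rng.exponential(1, 20), "b": rng.normal(0, 1, 20)})
        res = compare_groups(t, "welch_t")
        assert set(res.normality["group"]) == {"a", "b"}
        assert res.design == "welch_t"

    def test_insufficient_groups(self):
        with pytest.raises(ValueError):
            compare_groups(self.table({"a": [1, 2, 3]}), "welch_t")


class TestFoldChange:
    def test_point_estimates(self):
        assert fold_change([6.0] * 5, [1.0] * 5).estimate == pytest.approx(6.0)

    def test_equal_groups_ci_contains_one(self):
        rng = np.random.default_rng(11)
        x = rng.normal(5, 0.5, 9)
        res = fold_change(x, x)
        assert res.estimate == pytest.approx(1.0)
        assert res.contains(1.0)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(6, 1, 9), rng.normal(1, 0.2, 9)
        r1 = fold_change(a, b, seed=77)
        r2 = fold_change(a, b, seed=77)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_zero_denominator(self):
        with pytest.raises(ZeroDivisionError):
            fold_change([1.0, 2.0], [0.0, 0.0])
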