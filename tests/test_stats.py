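"""Cohort statistics: MOPP, power analysis, ANOVA, t-tests, regressions
and the table builders."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import omagperf as op
from omagperf.stats import (
    anova_oneway,
    build_tables,
    compute_mopp,
    power_two_sample_t,
    sample_size_two_group,
    ttest_two_group,
    univariate_regression,
)


class TestMOPP:
    def test_textbook_example(self):
        # MAP = 80 + 40/3 = 93.333; MOPP = 2/3*(93.333 - 15) = 52.222
        assert compute_mopp(120, 80, 15) == pytest.approx(52.2222, abs=1e-3)

    def test_equal_pressures_collapse(self):
        assert compute_mopp(90, 90, 12) == pytest.approx(2 / 3 * (90 - 12))

    def test_zero_perfusion_pressure(self):
        assert compute_mopp(120, 80, 93.3333333333) == pytest.approx(0.0, abs=1e-9)

    def test_inverted_pressures_rejected(self):
        with pytest.raises(ValueError, match="systolic"):
            compute_mopp(70, 80, 10)


class TestSampleSize:
    def test_study_design_inputs_give_28(self):
        assert sample_size_two_group(0.300, 0.06, 0.15, power=0.80, alpha=0.05) == 28

    def test_larger_difference_needs_fewer_eyes(self):
        n1 = sample_size_two_group(0.300, 0.06, 0.15)
        n2 = sample_size_two_group(0.300, 0.06, 0.30)
        assert n2 < n1

    def test_zero_difference_rejected(self):
        with pytest.raises(ValueError, match="infinite"):
            sample_size_two_group(0.300, 0.06, 0.0)

    def test_noncentral_t_method_at_least_normal(self):
        n_z = sample_size_two_group(0.300, 0.06, 0.15, method="normal")
        n_t = sample_size_two_group(0.300, 0.06, 0.15, method="noncentral_t")
        assert n_t >= n_z
        assert power_two_sample_t(n_t, 0.045, 0.06) >= 0.80

    def test_monte_carlo_power_at_28(self):
        # simulated rejection rate at delta=0.045, sd=0.06, n=28 per group
        rng = np.random.default_rng(0)
        reps = 10_000
        a = rng.normal(0.300, 0.06, (reps, 28))
        b = rng.normal(0.345, 0.06, (reps, 28))
        t, p = sps.ttest_ind(a, b, axis=1)
        assert abs((p < 0.05).mean() - 0.80) <= 0.03


def three_group_table():
    return pd.DataFrame({
        "group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
        "v": [1, 2, 3, 2, 3, 4, 3, 4, 5],
    })


class TestAnova:
    def test_null_by_construction(self):
        t = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                          "v": [2.0] * 9})
        res = anova_oneway(t, "v")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_matches_sums_of_squares_oracle(self):
        t = three_group_table()
        res = anova_oneway(t, "v")
        # hand-computed: group means 2,3,4; grand 3; SSB=3*(1+0+1)=6,
        # SSW=2+2+2=6; F=(6/2)/(6/6)=3; p from F(2,6)
        assert res.statistic == pytest.approx(3.0)
        assert res.pvalue == pytest.approx(sps.f.sf(3.0, 2, 6))
        # and agrees with scipy's implementation
        f, p = sps.f_oneway(*[g["v"].to_numpy() for _, g in t.groupby("group")])
        assert res.statistic == pytest.approx(f)
        assert res.pvalue == pytest.approx(p)

    def test_two_groups_equal_squared_t(self, rng):
        t = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 12,
                          "v": rng.standard_normal(22)})
        f = anova_oneway(t, "v").statistic
        tt = ttest_two_group(t, "v").statistic
        assert f == pytest.approx(tt ** 2, rel=1e-10)

    def test_small_group_rejected(self):
        t = pd.DataFrame({"group": ["a", "a", "b"], "v": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_oneway(t, "v")

    def test_group_summaries_have_ordered_cis(self):
        res = anova_oneway(three_group_table(), "v")
        for s in res.groups.values():
            assert s.ci_low <= s.mean <= s.ci_high


class TestTTest:
    def test_identical_groups(self):
        t = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "v": [1, 2, 3, 1, 2, 3]})
        res = ttest_two_group(t, "v")
        assert res.statistic == pytest.approx(0.0)
        assert res.pvalue == pytest.approx(1.0)

    def test_closed_form_pooled_oracle(self):
        t = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "v": [1, 2, 3, 2, 3, 4]})
        res = ttest_two_group(t, "v", mode="pooled")
        # pooled sd = 1, se = sqrt(2/3), t = -1/se = -1.2247
        assert res.statistic == pytest.approx(-np.sqrt(1.5), rel=1e-6)
        assert res.pvalue == pytest.approx(0.2879, abs=5e-4)

    def test_welch_equals_pooled_for_balanced_equal_variance(self, rng):
        x = rng.standard_normal(10)
        t = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10,
                          "v": np.r_[x, x + 0.5]})
        pooled = ttest_two_group(t, "v", mode="pooled").statistic
        welch = ttest_two_group(t, "v", mode="welch").statistic
        assert pooled == pytest.approx(welch, rel=1e-12)

    def test_constant_equal_groups_convention(self):
        t = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3, "v": [2.0] * 6})
        with pytest.warns(UserWarning, match="constant"):
            res = ttest_two_group(t, "v")
        assert res.statistic == 0.0 and res.pvalue == 1.0

    def test_group_selection(self):
        t = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3,
                          "v": list(range(9))})
        res = ttest_two_group(t, "v", groups=("a", "c"))
        assert set(res.groups) == {"a", "c"}


class TestRegression:
    def test_perfect_fit(self):
        t = pd.DataFrame({"x": [1, 2, 3, 4, 5], "y": [2, 4, 6, 8, 10]})
        res = univariate_regression(t, "x", "y")
        assert res.r_squared == pytest.approx(1.0)
        assert res.extra["slope"] == pytest.approx(2.0)

    def test_orthogonal_gives_zero_r2(self):
        t = pd.DataFrame({"x": [-1, 0, 1, -1, 0, 1], "y": [1, -2, 1, 1, -2, 1]})
        res = univariate_regression(t, "x", "y")
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_population_r2_is_squared_correlation(self):
        rng = np.random.default_rng(5)
        n = 10_000
        x = rng.standard_normal(n)
        y = 0.4 * x + np.sqrt(1 - 0.16) * rng.standard_normal(n)
        res = univariate_regression(pd.DataFrame({"x": x, "y": y}), "x", "y")
        assert res.r_squared == pytest.approx(0.16, abs=0.02)
        assert res.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, abs=1e-12)

    def test_constant_predictor_rejected(self):
        t = pd.DataFrame({"x": [1.0, 1.0, 1.0], "y": [1, 2, 3]})
        with pytest.raises(ValueError, match="constant"):
            univariate_regression(t, "x", "y")


class TestBuildTables:
    @pytest.fixture(scope="class")
    def cohort(self):
        return op.generate_cohort(op.default_cohort_spec(
            group_sizes={"normal": 28, "POAG": 30, "NTG": 31}, seed=3))

    def test_shapes_mirror_the_study_tables(self, cohort):
        tables = build_tables(cohort)
        assert len(tables["table2"]) == 3                      # three metrics
        assert {"normal", "POAG", "NTG"} <= set(tables["table2"].columns)
        assert "anova_p" in tables["table2"].columns
        assert len(tables["table4"]) == 3
        poag5 = tables["table5"].query("group == 'POAG'")
        assert len(poag5) == 7                                 # 7 regressors
        assert {"flux_r2", "vessel_density_r2", "normalized_flux_r2"} <= set(poag5.columns)

    def test_normal_group_has_no_visual_field_rows(self, cohort):
        t5 = build_tables(cohort)["table5"]
        assert "vf_md" not in set(t5.query("group == 'normal'")["variable"])

    def test_single_group_drops_anova_with_warning(self, cohort):
        single = cohort[cohort["group"] == "POAG"]
        with pytest.warns(UserWarning, match="single-group"):
            tables = build_tables(single)
        assert "anova_p" not in tables["table2"].columns

    def test_csv_output_is_deterministic(self, cohort, tmp_path):
        build_tables(cohort, out_dir=tmp_path / "a")
        build_tables(cohort, out_dir=tmp_path / "b")
        for name in ("table1", "table2", "table4", "table5"):
            assert (tmp_path / "a" / f"{name}.csv").read_bytes() == \
                   (tmp_path / "b" / f"{name}.csv").read_bytes()
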