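"""Clinical derived variables, group comparisons, and rank correlations."""

import math

import numpy as np
import pingouin
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import dtialps as d
from dtialps import cohort_stats as cs
from dtialps.types import ValidationError


class TestDerivedVariables:
    def test_desaturation_depth_reproduces_reported_value(self):
        assert d.delta_sao2(94.6, 78.5) == pytest.approx(16.1)

    def test_equal_baseline_and_nadir_give_zero(self):
        assert d.delta_sao2(91.0, 91.0) == 0.0

    def test_nadir_above_baseline_kept_negative_with_warning(self):
        with pytest.warns(UserWarning, match="exceeds baseline"):
            assert d.delta_sao2(90.0, 95.0) == pytest.approx(-5.0)

    def test_out_of_range_saturation_rejected(self):
        with pytest.raises(ValidationError):
            d.delta_sao2(101.0, 80.0)

    def test_bp_average_reproduces_both_group_values(self):
        assert d.bp_average(126.3, 79.5) == pytest.approx(102.9)
        assert d.bp_average(115.1, 73.7) == pytest.approx(94.4)

    @pytest.mark.parametrize(
        "ahi,category",
        [
            (0.0, "none"),
            (4.99, "none"),
            (5.0, "mild"),
            (14.9, "mild"),
            (15.0, "moderate"),
            (30.0, "moderate"),
            (30.1, "severe"),
            (35.4, "severe"),
        ],
    )
    def test_ahi_severity_bands(self, ahi, category):
        assert d.classify_ahi(ahi) == category

    def test_negative_ahi_rejected(self):
        with pytest.raises(ValidationError):
            d.classify_ahi(-1.0)

    @pytest.mark.parametrize(
        "psqi,ess,expected",
        [
            (8.5, 8.5, (True, False)),
            (5.0, 10.0, (False, False)),  # thresholds are strict
            (4.5, 4.7, (False, False)),
            (6.0, 11.0, (True, True)),
        ],
    )
    def test_sleep_score_abnormality_flags(self, psqi, ess, expected):
        assert d.flag_sleep_scores(psqi, ess) == expected


def _toy_records(osa_vals, ctl_vals, variable="bmi"):
    recs = []
    for i, v in enumerate(osa_vals):
        recs.append(
            d.SubjectRecord(
                id=f"o{i}", group="OSA", age=50, sex="male", **{variable: v}
            )
        )
    for i, v in enumerate(ctl_vals):
        recs.append(
            d.SubjectRecord(
                id=f"c{i}", group="control", age=50, sex="male", **{variable: v}
            )
        )
    return recs


class TestDemographics:
    def test_identical_groups_show_no_difference(self):
        recs = _toy_records([25, 26, 27, 28], [25, 26, 27, 28])
        table = d.demographics_table(recs)
        row = table[table.variable == "bmi"].iloc[0]
        assert row.osa_mean == row.control_mean
        assert row.p > 0.99

    def test_sex_chi_square_matches_hand_computed_pearson_statistic(self):
        # 35:24 vs 34:28 male:female
        recs = []
        for grp, males, females in (("OSA", 35, 24), ("control", 34, 28)):
            for i in range(males):
                recs.append(d.SubjectRecord(f"{grp}m{i}", grp, 50, "male"))
            for i in range(females):
                recs.append(d.SubjectRecord(f"{grp}f{i}", grp, 50, "female"))
        table = d.demographics_table(recs)
        p = table[table.variable == "sex_male_female"].iloc[0].p
        # brute-force Pearson chi-square from expected counts
        obs = np.array([[35, 24], [34, 28]])
        exp = np.outer(obs.sum(1), obs.sum(0)) / obs.sum()
        chi2 = ((obs - exp) ** 2 / exp).sum()
        p_ref = stats.chi2.sf(chi2, 1)
        assert p == pytest.approx(p_ref, rel=1e-12)
        assert p > 0.05  # not significant, as reported

    def test_summary_statistics_ttest_equals_raw_data_ttest(self, rng):
        a = rng.normal(8.5, 4.1, 57)
        b = rng.normal(4.5, 2.6, 62)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t_sum, p_sum = cs.ttest_from_stats(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b)
        )
        assert t_sum == pytest.approx(t_raw, rel=1e-12)
        assert p_sum == pytest.approx(p_raw, rel=1e-12)

    def test_missing_values_excluded_with_reported_n(self):
        recs = _toy_records([8, 9, None, 7], [4, 5, 6, None], variable="psqi")
        table = d.demographics_table(recs)
        row = table[table.variable == "psqi"].iloc[0]
        assert row.osa_n == 3 and row.control_n == 3

    def test_zero_variance_in_both_groups_reports_undefined_p(self):
        recs = _toy_records([5, 5, 5], [7, 7, 7])
        table = d.demographics_table(recs)
        row = table[table.variable == "bmi"].iloc[0]
        assert math.isnan(row.p)


class TestAncova:
    def _cohort(self, rng, delta=0.0, n1=40, n2=40):
        vals = np.concatenate(
            [rng.normal(1.34 + delta, 0.11, n1), rng.normal(1.34, 0.11, n2)]
        )
        group = ["OSA"] * n1 + ["control"] * n2
        age = rng.normal(50, 10, n1 + n2)
        sex = rng.choice(["male", "female"], n1 + n2).tolist()
        return vals, group, age, sex

    def test_constant_covariates_reduce_exactly_to_pooled_ttest(self, rng):
        vals, group, _, _ = self._cohort(rng, delta=0.05)
        n = len(vals)
        cmp = d.ancova_group_compare(vals, group, [50.0] * n, ["male"] * n)
        t, p = stats.ttest_ind(vals[:40], vals[40:], equal_var=True)
        assert cmp.raw_p == pytest.approx(p, rel=1e-10)
        assert cmp.covariates == ()
        assert cmp.adjusted_means["OSA"] == pytest.approx(vals[:40].mean(), rel=1e-12)

    def test_group_p_matches_independent_ancova_implementation(self, rng):
        vals, group, age, sex = self._cohort(rng, delta=0.06)
        cmp = d.ancova_group_compare(vals, group, age, sex, family_size=3)
        import pandas as pd

        df = pd.DataFrame(
            {
                "y": vals,
                "group": [1 if g == "OSA" else 0 for g in group],
                "age": age,
                "sex": [1 if s == "female" else 0 for s in sex],
            }
        )
        ref = pingouin.ancova(data=df, dv="y", between="group", covar=["age", "sex"])
        p_ref = float(ref.loc[ref.Source == "group", "p_unc"].iloc[0])
        assert cmp.raw_p == pytest.approx(p_ref, rel=1e-6)
        assert cmp.adjusted_p == pytest.approx(min(1, 3 * cmp.raw_p), rel=1e-12)

    def test_adjusted_means_remove_covariate_imbalance(self, rng):
        # group difference entirely explained by an age trend
        n = 60
        age = np.concatenate([rng.normal(60, 3, n), rng.normal(40, 3, n)])
        vals = 1.0 + 0.01 * age + rng.normal(0, 1e-6, 2 * n)
        group = ["OSA"] * n + ["control"] * n
        cmp = d.ancova_group_compare(vals, group, age, ["male"] * 2 * n)
        assert cmp.adjusted_means["OSA"] == pytest.approx(
            cmp.adjusted_means["control"], abs=1e-4
        )
        assert cmp.raw_p > 0.05

    def test_collinear_covariate_named_in_error(self):
        vals = [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]
        group = ["OSA", "OSA", "OSA", "control", "control", "control"]
        # age numerically identical to the sex coding -> collinear
        age = [1.0, 0.0, 1.0, 0.0, 1.0, 0.0]
        sex = ["female", "male", "female", "male", "female", "male"]
        with pytest.raises(ValidationError, match="age|sex"):
            d.ancova_group_compare(vals, group, age, sex)

    def test_bonferroni_monotone_capped_and_linear_below_cap(self):
        assert cs.bonferroni(0.01, 3) == pytest.approx(0.03)
        assert cs.bonferroni(0.5, 3) == 1.0
        ps = [0.001, 0.01, 0.02, 0.4]
        adj = [cs.bonferroni(p, 4) for p in ps]
        assert adj == sorted(adj)


class TestSpearman:
    def test_strictly_monotone_pairs_give_unit_magnitude(self):
        up = d.spearman([1, 2, 3, 4], [10, 20, 30, 40])
        down = d.spearman([1, 2, 3, 4], [8, 6, 4, 2])
        assert up.r == pytest.approx(1.0)
        assert down.r == pytest.approx(-1.0)

    def test_tied_data_matches_library_tie_correction(self, rng):
        x = rng.integers(0, 5, 40).astype(float)  # heavy ties
        y = x + rng.integers(0, 3, 40)
        res = d.spearman(x, y)
        ref_r, ref_p = stats.spearmanr(x, y)
        assert res.r == pytest.approx(ref_r, abs=1e-12)
        assert res.p == pytest.approx(ref_p, rel=1e-9)

    def test_pairwise_deletion_of_missing_pairs(self):
        res = d.spearman([1, 2, None, 4, 5], [2, None, 6, 8, 10])
        assert res.n == 3
        assert res.r == pytest.approx(1.0)

    def test_constant_vector_reported_as_not_estimable(self):
        res = d.spearman([1, 1, 1, 1], [1, 2, 3, 4])
        assert not res.estimable and res.r is None

    def test_fewer_than_three_pairs_rejected(self):
        with pytest.raises(ValidationError):
            d.spearman([1, 2], [3, 4])

    def test_exact_permutation_p_for_perfect_correlation(self):
        # among 4! rank permutations exactly two reach |r| = 1
        res = d.spearman([1, 2, 3, 4], [1, 2, 3, 4], exact=True)
        assert res.p == pytest.approx(2 / 24)

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(
            st.integers(min_value=-50, max_value=50),
            min_size=5,
            max_size=20,
            unique=True,
        )
    )
    def test_invariant_under_strictly_monotone_transforms(self, xs):
        xs = [float(v) for v in xs]
        ys = [math.sin(0.1 * v) + 0.3 * v for v in xs]  # arbitrary response
        base = d.spearman(xs, ys)
        warped = d.spearman([math.exp(v / 60) for v in xs], [3 * v + 1 for v in ys])
        assert warped.r == pytest.approx(base.r, abs=1e-12)


class TestSeverityPanel:
    def test_default_panel_reports_the_four_published_pairs(self):
        recs, _ = d.simulate_cohort(d.CohortSpec(n_osa=30, n_control=20, seed=8))
        results = d.severity_correlation_panel(recs)
        pairs = {(r.clinical_variable, r.roi, r.component) for r in results}
        assert pairs == {
            ("ess", "projection", "dxy"),
            ("sao2_nadir", "projection", "dxx"),
            ("delta_sao2", "projection", "dxx"),
            ("ahi", "association", "dzz"),
        }
        assert all(r.estimable and r.n == 30 for r in results)

    def test_independent_variables_show_near_zero_mean_correlation(self):
        rs = []
        for seed in range(200):
            recs, _ = d.simulate_cohort(d.CohortSpec(n_osa=30, n_control=2, seed=seed))
            res = d.severity_correlation_panel(recs)
            rs.append([r.r for r in res][3])  # ahi vs dzz assoc, unplanted
        assert abs(np.mean(rs)) < 0.05

    def test_all_missing_ess_leaves_other_rows_estimable(self):
        recs, _ = d.simulate_cohort(d.CohortSpec(n_osa=20, n_control=5, seed=1))
        for r in recs:
            r.ess = None
        results = d.severity_correlation_panel(recs)
        by_var = {r.clinical_variable: r for r in results}
        assert not by_var["ess"].estimable
        assert by_var["ahi"].estimable and by_var["sao2_nadir"].estimable

    def test_full_grid_covers_all_components_both_rois(self):
        recs, _ = d.simulate_cohort(d.CohortSpec(n_osa=15, n_control=5, seed=2))
        results = d.severity_correlation_panel(recs, full_grid=True)
        assert len(results) == 5 * 2 * 6


def test_p_value_formatting_floors_below_a_thousandth():
    assert cs.format_p(0.0004) == "<0.001"
    assert cs.format_p(0.031) == "0.031"
    assert cs.format_p(float("nan")) == "undefined"
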