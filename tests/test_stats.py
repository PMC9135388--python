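import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import hcineq.schema as schema
from hcineq import (GeneratorConfig, TwoByTwoTable, build_two_by_two,
                    demographic_comparison, fisher_p, fit_adjusted_logistic,
                    generate_cohort, impute_covariates, odds_ratio,
                    significance_label, two_by_two_for_item)
from hcineq.stats import DegenerateTableError, format_p


def exhaustive_fisher_p(table: TwoByTwoTable) -> float:
    """Oracle: full hypergeometric enumeration over the fixed margins,
    summing the probabilities of all outcomes no more likely than the
    observed table."""
    row1, row2 = table.a + table.b, table.c + table.d
    col1 = table.a + table.c
    n = row1 + row2

    def prob(a):
        return (math.comb(row1, a) * math.comb(row2, col1 - a)
                / math.comb(n, col1))

    p_obs = prob(table.a)
    total = 0.0
    for a in range(max(0, col1 - row2), min(row1, col1) + 1):
        p = prob(a)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestOddsRatio:
    def test_published_access_row(self):
        """Counts reconstructed from the published access item reproduce
        its printed OR."""
        est = odds_ratio(TwoByTwoTable(693, 587, 1041, 322))
        assert round(est.or_point, 3) == 0.365
        assert est.ci_low < est.or_point < est.ci_high

    def test_published_meltdown_prescription_row(self):
        est = odds_ratio(TwoByTwoTable(116, 1106, 20, 1207))
        assert round(est.or_point, 3) == 6.330

    @pytest.mark.parametrize("k", [1, 5, 40])
    def test_symmetric_table_is_unity(self, k):
        assert odds_ratio(TwoByTwoTable(k, k, k, k)).or_point == 1.0

    @given(a=st.integers(1, 60), b=st.integers(1, 60),
           c=st.integers(1, 60), d=st.integers(1, 60))
    @settings(max_examples=40, deadline=None)
    def test_group_swap_inverts_or(self, a, b, c, d):
        direct = odds_ratio(TwoByTwoTable(a, b, c, d)).or_point
        swapped = odds_ratio(TwoByTwoTable(c, d, a, b)).or_point
        assert direct == pytest.approx(1.0 / swapped, rel=1e-12)

    def test_exposure_outcome_transposition_symmetry(self):
        """The odds ratio (and Fisher's exact p) are symmetric in exposure
        and outcome: transposing the 2x2 table leaves both unchanged.  The
        interpretation changes; the number does not."""
        t = TwoByTwoTable(5, 10, 2, 40)
        transposed = TwoByTwoTable(5, 2, 10, 40)
        assert (odds_ratio(t).or_point ==
                pytest.approx(odds_ratio(transposed).or_point))
        assert fisher_p(t) == pytest.approx(fisher_p(transposed))

    def test_zero_cell_continuity_corrected_and_flagged(self):
        est = odds_ratio(TwoByTwoTable(5, 0, 3, 7))
        assert est.continuity_corrected
        assert np.isfinite(est.or_point) and est.or_point > 0

    def test_conditional_mle_close_to_cross_product(self):
        t = TwoByTwoTable(693, 587, 1041, 322)
        cmle = odds_ratio(t, method="conditional-mle")
        xp = odds_ratio(t, method="cross-product")
        assert cmle.or_point == pytest.approx(xp.or_point, rel=0.01)
        assert cmle.method == "conditional-mle"

    @given(a=st.integers(1, 40), b=st.integers(1, 40),
           c=st.integers(1, 40), d=st.integers(1, 40))
    @settings(max_examples=40, deadline=None)
    def test_wald_ci_excludes_one_iff_z_significant(self, a, b, c, d):
        est = odds_ratio(TwoByTwoTable(a, b, c, d))
        se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        z_sig = abs(np.log(est.or_point)) > 1.959963984540054 * se
        excludes_one = est.ci_low > 1.0 or est.ci_high < 1.0
        assert z_sig == excludes_one


class TestFisher:
    def test_balanced_unit_table(self):
        assert fisher_p(TwoByTwoTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_diagonal_three(self):
        # margins 3/3 over N=6: only the two extreme tables are as unlikely
        assert fisher_p(TwoByTwoTable(3, 0, 0, 3)) == pytest.approx(0.1)

    def test_matches_enumeration_oracle_small_tables(self):
        for a, b, c, d in itertools.product(range(5), repeat=4):
            if a + b == 0 or c + d == 0 or a + b + c + d == 0:
                continue
            t = TwoByTwoTable(a, b, c, d)
            assert fisher_p(t) == pytest.approx(exhaustive_fisher_p(t),
                                                rel=1e-9, abs=1e-12)


class TestBuildTwoByTwo:
    def test_counts_non_missing_only(self):
        binary = pd.Series(["endorse", "endorse", "reject", None,
                            "endorse", "reject", "reject", "reject"])
        case = pd.Series([True, True, True, True, False, False, False, False])
        t = build_two_by_two(binary, case)
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 3)

    def test_all_missing_degenerate(self):
        binary = pd.Series([None, None, None, None], dtype=object)
        case = pd.Series([True, True, False, False])
        with pytest.raises(DegenerateTableError):
            build_two_by_two(binary, case)

    def test_published_counts_reconstructed_from_n_and_pct(self):
        # denominator = round(N / %) recovers the answering group sizes
        n_case = round(693 / 0.5414)
        n_control = round(1041 / 0.7638)
        assert (n_case, n_control) == (1280, 1363)
        t = TwoByTwoTable(693, n_case - 693, 1041, n_control - 1041)
        assert (t.a, t.b, t.c, t.d) == (693, 587, 1041, 322)


class TestSignificanceLabel:
    @pytest.mark.parametrize("p,label", [
        (5e-4, "*"), (0.05, ""), (2.22e-16, "***"),
        (1e-3, ""), (9.99e-4, "*"), (1e-4, "*"), (9.9e-5, "**"),
        (1e-5, "**"), (9.9e-6, "***"), (0.0, "***"), (1.0, ""),
    ])
    def test_half_open_thresholds(self, p, label):
        assert significance_label(p) == label

    def test_display_floor(self):
        assert format_p(1e-20) == "< 2.22e-16"
        assert format_p(0.25).startswith("0.25")


class TestImputation:
    def test_zero_missingness_gives_identical_copies(self, cohort):
        complete = cohort.copy()
        for cov in (schema.ETHNICITY, schema.EDUCATION, schema.COUNTRY):
            complete[cov] = complete[cov].fillna("filler")
        imps = impute_covariates(complete, m=4, seed=1)
        assert imps.m == 4
        for table in imps.tables:
            assert table[schema.ETHNICITY].equals(complete[schema.ETHNICITY])

    def test_non_missing_cells_never_altered(self, cohort):
        imps = impute_covariates(cohort, m=3, seed=2)
        for cov in imps.variables:
            observed = cohort[cov].notna()
            for table in imps.tables:
                assert (table.loc[observed, cov] ==
                        cohort.loc[observed, cov]).all()
                assert table[cov].notna().all()

    def test_imputed_marginal_close_to_truth(self):
        cfg = GeneratorConfig(
            n_case=2500, n_control=2500, n_duplicates=0, n_incomplete=0,
            n_unconfirmed=0, seed=4,
            covariate_missing_rates={schema.ETHNICITY: 0.05})
        frame = generate_cohort(cfg).frame
        observed_truth = frame[schema.ETHNICITY].dropna().eq("white").mean()
        imps = impute_covariates(frame, m=5, seed=9)
        pooled = np.mean([(t[schema.ETHNICITY] == "white").mean()
                          for t in imps.tables])
        assert pooled == pytest.approx(observed_truth, abs=0.03)

    def test_majority_missing_refused(self, cohort):
        broken = cohort.copy()
        broken.loc[broken.sample(frac=0.7, random_state=0).index,
                   schema.ETHNICITY] = None
        with pytest.raises(ValueError, match="refusing to impute"):
            impute_covariates(broken, m=2, seed=0)


class TestAdjustedLogistic:
    def test_zero_missingness_pooling_degenerates_to_complete_case(self, cohort):
        import statsmodels.api as sm

        from hcineq.stats import _design_matrix, ADJUSTMENT_COVARIATES

        complete = cohort.copy()
        for cov in (schema.ETHNICITY, schema.EDUCATION, schema.COUNTRY):
            complete[cov] = complete[cov].fillna("filler")
        case = (complete[schema.AUTISM_STATUS] ==
                schema.CONFIRMED_AUTISTIC).astype(float)
        exposure = complete[schema.condition_col("anxiety")].astype(float)
        imps = impute_covariates(complete, m=5, seed=3)
        pooled = fit_adjusted_logistic(case, exposure, complete, imps)

        X = _design_matrix(complete, exposure, ADJUSTMENT_COVARIATES)
        direct = sm.GLM(case.to_numpy(), X.to_numpy(),
                        family=sm.families.Binomial()).fit()
        assert pooled.or_point == pytest.approx(
            float(np.exp(direct.params[1])), rel=1e-6)
        assert not pooled.separation_flag

    def test_separated_covariate_level_flags_and_withholds(self):
        rng = np.random.default_rng(0)
        n = 300
        frame = pd.DataFrame({
            schema.AGE: rng.normal(40, 10, n).round(),
            schema.ETHNICITY: np.where(np.arange(n) < 150, "white", "non-white"),
            schema.EDUCATION: "University Undergraduate",
            schema.COUNTRY: "United Kingdom",
        })
        outcome = pd.Series((np.arange(n) < 150).astype(float))  # = ethnicity
        exposure = pd.Series(rng.random(n))
        res = fit_adjusted_logistic(outcome, exposure, frame)
        assert res.separation_flag
        assert np.isnan(res.or_point)

    def test_recovers_planted_conditional_or(self):
        cfg = GeneratorConfig(
            n_case=2000, n_control=2000, n_duplicates=0, n_incomplete=0,
            n_unconfirmed=0, item_missing_rate=0.0,
            covariate_missing_rates={}, seed=17,
            item_effects={"ax_idea": (0.3, 4.0)},
            shutdown_effects={}, meltdown_effects={}, condition_effects={})
        frame = generate_cohort(cfg).frame
        case = (frame[schema.AUTISM_DIAGNOSIS] == "yes").astype(float)
        endorsed = frame["item_ax_idea"].isin(schema.LIKERT_ENDORSE)
        exposure = endorsed.astype(float).where(frame["item_ax_idea"].notna())
        res = fit_adjusted_logistic(case, exposure, frame)
        assert res.ci_low <= 4.0 <= res.ci_high
        assert 3.2 <= res.or_point <= 5.0


class TestDemographics:
    def test_identical_groups_chi_square_unity(self):
        frame = pd.DataFrame({
            schema.AUTISM_STATUS: [schema.CONFIRMED_AUTISTIC] * 4
            + [schema.CONFIRMED_NON_AUTISTIC] * 4,
            schema.SEX_AT_BIRTH: ["F", "F", "M", "M"] * 2,
            schema.GENDER: ["female", "female", "male", "male"] * 2,
            schema.ETHNICITY: ["white"] * 8,
            schema.EDUCATION: ["University Undergraduate"] * 8,
            schema.COUNTRY: ["United Kingdom"] * 8,
            schema.AGE: [30, 40, 30, 40] * 2,
            schema.AQ10: [5, 5, 5, 5] * 2,
        })
        table = demographic_comparison(frame)
        sex_row = table[(table.variable == schema.SEX_AT_BIRTH)
                        & (table.test == "chi-square")].iloc[0]
        assert sex_row.p_value == pytest.approx(1.0)

    def test_planted_trait_shift_detected(self):
        rng = np.random.default_rng(5)
        n = 1000
        frame = pd.DataFrame({
            schema.AUTISM_STATUS: [schema.CONFIRMED_AUTISTIC] * n
            + [schema.CONFIRMED_NON_AUTISTIC] * n,
            schema.SEX_AT_BIRTH: "F", schema.GENDER: "female",
            schema.ETHNICITY: "white",
            schema.EDUCATION: "University Undergraduate",
            schema.COUNTRY: "United Kingdom",
            schema.AGE: rng.normal(40, 10, 2 * n).round(),
            schema.AQ10: np.clip(np.r_[rng.normal(8, 2, n),
                                       rng.normal(4, 2, n)].round(), 0, 10),
        })
        table = demographic_comparison(frame)
        aq_row = table[table.variable == schema.AQ10].iloc[0]
        assert aq_row.p_value < 1e-10
        assert aq_row.sig == "***"

    def test_category_counts_sum_to_group_sizes(self, cohort):
        table = demographic_comparison(cohort)
        n_case = (cohort[schema.AUTISM_STATUS] ==
                  schema.CONFIRMED_AUTISTIC).sum()
        levels = table[(table.variable == schema.SEX_AT_BIRTH)
                       & (table.test == "count (pct)")]
        assert levels.case_value.sum() == n_case  # sex is never missing
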