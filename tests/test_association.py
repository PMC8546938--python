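import numpy as np
import pytest

from screenseven import reference
from screenseven.association import (
    ContingencyTable,
    chi_square,
    crosstab,
    crude_or,
    fit_adjusted_model,
    odds_ratio_2x2,
    pairwise_subgroup_labels,
    reconstruct_counts,
    table_from_margins,
)
from screenseven.errors import StatisticalError, ValidationError


def two_level_table(a, b, c, d, name="cov"):
    """counts: level1 (low=b, high=a), reference (low=d, high=c)."""
    return ContingencyTable(
        covariate=name, levels=("ref", "lv"),
        counts=np.array([[d, c], [b, a]]), reference="ref",
    )


class TestChiSquare:
    def test_identical_proportions_give_zero(self):
        t = two_level_table(10, 10, 10, 10)
        chi2, df, p = chi_square(t)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_hand_formula_on_2x2(self):
        # chi2 = n(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d)) on [[20,10],[10,20]]
        counts = np.array([[20, 10], [10, 20]])
        chi2, df, p = chi_square(counts)
        assert df == 1
        assert chi2 == pytest.approx(60 * (400 - 100) ** 2 / 30**4)
        assert chi2 == pytest.approx(20 / 3)

    def test_hand_formula_on_random_2x2(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            a, b, c, d = rng.integers(1, 80, size=4)
            chi2, _, _ = chi_square(np.array([[a, b], [c, d]]))
            n = a + b + c + d
            oracle = n * (a * d - b * c) ** 2 / (
                (a + b) * (c + d) * (a + c) * (b + d))
            assert chi2 == pytest.approx(oracle, rel=1e-10)

    def test_invariant_to_transpose(self):
        counts = np.array([[12, 30], [44, 9]])
        assert chi_square(counts)[0] == pytest.approx(
            chi_square(counts.T)[0])

    def test_single_level_refused(self):
        t = ContingencyTable("c", ("only",), np.array([[5, 5]]), "only")
        with pytest.raises(StatisticalError):
            chi_square(t)


class TestCrudeOr:
    def test_balanced_table_or_one(self):
        est = crude_or(two_level_table(10, 10, 10, 10), "lv")
        assert est.odds_ratio == pytest.approx(1.0)
        assert est.ci_low < 1 < est.ci_high

    def test_level_equal_reference_refused(self):
        with pytest.raises(ValidationError):
            crude_or(two_level_table(1, 1, 1, 1), "ref")

    def test_matches_cross_product_oracle_on_random_tables(self):
        rng = np.random.default_rng(1)
        for _ in range(1000):
            a, b, c, d = rng.integers(1, 200, size=4)
            or_, lo, hi, cells, corrected = odds_ratio_2x2(a, b, c, d)
            assert not corrected
            assert or_ == pytest.approx((a * d) / (b * c), rel=1e-12)
            assert lo < or_ < hi

    def test_agrees_with_scipy_sample_odds_ratio(self):
        from scipy.stats.contingency import odds_ratio as scipy_or

        rng = np.random.default_rng(2)
        for _ in range(50):
            a, b, c, d = rng.integers(1, 100, size=4)
            ours, *_ = odds_ratio_2x2(a, b, c, d)
            theirs = scipy_or([[a, b], [c, d]], kind="sample").statistic
            assert ours == pytest.approx(theirs, rel=1e-12)

    def test_zero_cell_gets_haldane_correction(self):
        or_, lo, hi, cells, corrected = odds_ratio_2x2(0, 10, 5, 10)
        assert corrected
        assert cells == (0.5, 10.5, 5.5, 10.5)
        assert or_ == pytest.approx((0.5 * 10.5) / (10.5 * 5.5))

    def test_no_events_anywhere_is_error(self):
        with pytest.raises(StatisticalError):
            odds_ratio_2x2(0, 10, 0, 10)

    def test_crosstab_then_or_consistent_with_cells(self, default_cohort):
        t = crosstab(default_cohort, "uses_touchscreen")
        est = crude_or(t, "yes")
        a, b, c, d = est.cells
        assert est.odds_ratio == pytest.approx((a * d) / (b * c))


class TestReconstructCounts:
    @pytest.mark.parametrize("n,pct,expected", [
        (313, 28.8, 90), (223, 34.5, 77), (100, 50.0, 50),
        (932, 20.4, 190), (426, 13.1, 56), (119, 48.7, 58),
    ])
    def test_printed_margin_reconstruction(self, n, pct, expected):
        assert reconstruct_counts(n, pct) == expected

    def test_ties_round_half_up(self):
        assert reconstruct_counts(10, 25.0) == 3  # 2.5 -> 3
        assert reconstruct_counts(200, 10.25) == 21  # 20.5 -> 21


class TestPairwiseSubgroupLabels:
    def test_identical_proportions_share_one_letter(self):
        t = ContingencyTable(
            "c", ("x", "y", "z"),
            np.array([[40, 10], [40, 10], [40, 10]]), "x",
        )
        labels = pairwise_subgroup_labels(t)
        assert set(labels.values()) == {"a"}

    def test_daycare_reconstruction_matches_published_pattern(self):
        marg = {lv: (v[0], v[2])
                for lv, v in reference.MARGINALS["daycare"].items()}
        t = table_from_margins("daycare", marg, "mother")
        labels = pairwise_subgroup_labels(t)
        assert labels["mother"] != labels["kindergarten"]
        assert labels["grandparent"] == labels["childminder"]

    def test_underpowered_extremes_share_letter(self):
        t = ContingencyTable(
            "c", ("x", "y", "z"),
            np.array([[4, 1], [3, 2], [1, 4]]), "x",
        )
        labels = pairwise_subgroup_labels(t)
        assert labels["x"] == labels["z"]

    def test_two_levels_refused(self):
        with pytest.raises(ValidationError):
            pairwise_subgroup_labels(two_level_table(5, 5, 5, 5))


class TestCrosstab:
    def test_default_cohort_marginals_near_study(self, default_cohort):
        t = crosstab(default_cohort, "maternal_age_band")
        pct = t.column_pct()
        assert pct["lt30"] == pytest.approx(25.1, abs=4.0)
        assert pct["ge30"] == pytest.approx(74.9, abs=4.0)
        assert t.n == len(default_cohort)

    def test_unknown_field_refused(self, small_cohort):
        with pytest.raises(ValidationError):
            crosstab(small_cohort, "shoe_size")

    def test_row_and_column_percentages(self):
        t = two_level_table(a=20, b=30, c=10, d=40)
        assert t.column_pct()["lv"] == pytest.approx(50.0)
        assert t.row_pct_high()["lv"] == pytest.approx(40.0)
        assert t.row_pct_high()["ref"] == pytest.approx(20.0)


class TestAdjustedModel:
    def test_default_cohort_directions_match_study(self, default_cohort):
        res = fit_adjusted_model(default_cohort)
        assert res.converged
        kind, _, _ = res.aor("daycare", "kindergarten")
        touch, _, _ = res.aor("uses_touchscreen", "yes")
        postpone, _, _ = res.aor("postponing_needs", "frequently")
        assert kind < 1  # kindergarten protective
        assert touch > 1  # touchscreen risk
        assert postpone > 1

    def test_reference_rows_carry_aor_one(self, default_cohort):
        res = fit_adjusted_model(default_cohort)
        refs = res.estimates[res.estimates.reference]
        assert (refs.aor == 1.0).all()

    def test_separation_raises_named_error(self, small_cohort):
        import dataclasses

        # force every rural record to be high-PSE by maxing its response
        from screenseven.survey import QuestionnaireResponse, ScreenTimeReport

        worst = QuestionnaireResponse(
            screen_time=ScreenTimeReport(5, 1, 5, 1), onset_age_months=6,
            meals_use="yes", bedtime_use="yes",
            inappropriate_content_kinds=3, co_viewing="rarely_ever",
            limits="set_not_obeyed",
        )
        rigged = [
            dataclasses.replace(r, settlement="rural", response=worst)
            if i < 10 else dataclasses.replace(r, settlement="urban")
            for i, r in enumerate(small_cohort)
        ]
        with pytest.raises(StatisticalError, match="settlement"):
            fit_adjusted_model(rigged, covariates=("settlement",))
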