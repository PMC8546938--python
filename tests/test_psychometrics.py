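import numpy as np
import pytest

from screenseven.errors import StatisticalError
from screenseven.psychometrics import (
    bartlett_sphericity,
    correlation_matrix,
    cronbach_alpha,
    item_matrix,
    kmo,
    pca_factors,
    validation_battery,
)


class TestCorrelationMatrix:
    def test_duplicated_item_has_unit_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=(200, 1)).astype(float)
        items = np.hstack([x, x, rng.integers(0, 3, size=(200, 5))])
        R = correlation_matrix(items)
        assert R[0, 1] == pytest.approx(1.0)
        assert np.allclose(R, R.T) and np.allclose(np.diag(R), 1.0)

    def test_anticorrelated_pair(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(100, 1))
        items = np.hstack([x, -x])
        assert correlation_matrix(items)[0, 1] == pytest.approx(-1.0)

    def test_independent_items_near_zero(self):
        rng = np.random.default_rng(2)
        items = rng.integers(0, 3, size=(10000, 7)).astype(float)
        R = correlation_matrix(items)
        off = R[~np.eye(7, dtype=bool)]
        assert np.abs(off).max() < 0.05

    def test_zero_variance_column_names_item(self):
        items = np.ones((50, 7))
        items[:, 1:] = np.random.default_rng(3).integers(0, 3, (50, 6))
        with pytest.raises(StatisticalError, match="s_time"):
            correlation_matrix(items)


class TestKmo:
    def test_identity_matrix_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="KMO"):
            overall, per_item = kmo(np.eye(7))
        assert overall == 0.0

    def test_matches_hand_computed_3x3(self):
        # R and its inverse worked explicitly through cofactors
        r12, r13, r23 = 0.5, 0.3, 0.2
        R = np.array([[1, r12, r13], [r12, 1, r23], [r13, r23, 1]])
        det = (1 * (1 - r23**2) - r12 * (r12 - r23 * r13)
               + r13 * (r12 * r23 - r13))
        cof = np.array([
            [1 - r23**2, -(r12 - r23 * r13), r12 * r23 - r13],
            [-(r12 - r13 * r23), 1 - r13**2, -(r23 - r12 * r13)],
            [r12 * r23 - r13, -(r23 - r13 * r12), 1 - r12**2],
        ])
        Rinv = cof.T / det
        d = np.sqrt(np.diag(Rinv))
        partial = -Rinv / np.outer(d, d)
        r2 = r12**2 + r13**2 + r23**2
        q2 = partial[0, 1]**2 + partial[0, 2]**2 + partial[1, 2]**2
        expected = (2 * r2) / (2 * r2 + 2 * q2)
        overall, _ = kmo(R)
        assert overall == pytest.approx(expected, rel=1e-12)

    def test_invariant_to_item_sign_flips(self, default_cohort):
        items = item_matrix(default_cohort[:400])
        R = correlation_matrix(items)
        flipped = items.copy()
        flipped[:, 2] = -flipped[:, 2]
        flipped[:, 5] = -flipped[:, 5]
        Rf = correlation_matrix(flipped)
        assert kmo(R)[0] == pytest.approx(kmo(Rf)[0], rel=1e-10)

    def test_default_cohort_in_vicinity_of_study_value(self, default_cohort):
        overall, _ = kmo(correlation_matrix(item_matrix(default_cohort)))
        assert 0.45 < overall < 0.8  # study reported 0.61


class TestBartlett:
    def test_identity_gives_zero_chi2_p_one(self):
        chi2, df, p = bartlett_sphericity(np.eye(7), n=500)
        assert chi2 == pytest.approx(0.0, abs=1e-10)
        assert p == pytest.approx(1.0)

    def test_df_is_21_for_seven_items(self):
        _, df, _ = bartlett_sphericity(np.eye(7), n=100)
        assert df == 21

    def test_correlated_items_strongly_rejected(self, default_cohort):
        R = correlation_matrix(item_matrix(default_cohort))
        chi2, df, p = bartlett_sphericity(R, n=len(default_cohort))
        assert p < 0.001
        assert chi2 > 100

    def test_invariant_to_item_order(self, default_cohort):
        items = item_matrix(default_cohort[:300])
        R = correlation_matrix(items)
        perm = np.random.default_rng(0).permutation(7)
        Rp = correlation_matrix(items[:, perm])
        c1, _, _ = bartlett_sphericity(R, n=300)
        c2, _, _ = bartlett_sphericity(Rp, n=300)
        assert c1 == pytest.approx(c2, rel=1e-10)


class TestPcaFactors:
    def test_identity_retains_nothing_under_strict_rule(self):
        res = pca_factors(np.eye(7))
        assert res.n_factors == 0

    def test_block_diagonal_recovers_blocks(self):
        R = np.eye(7)
        blocks = [(0, 1, 2), (3, 4), (5, 6)]
        for blk in blocks:
            for i in blk:
                for j in blk:
                    if i != j:
                        R[i, j] = 0.6
        res = pca_factors(R)
        assert res.n_factors == 3
        assign = res.factor_assignment
        for blk in blocks:
            assert len({assign[i] for i in blk}) == 1
        assert len({assign[b[0]] for b in blocks}) == 3

    def test_full_retention_reconstructs_correlation(self, default_cohort):
        R = correlation_matrix(item_matrix(default_cohort[:500]))
        res = pca_factors(R, n_factors=7)
        assert np.allclose(res.loadings @ res.loadings.T, R, atol=1e-10)

    def test_default_cohort_three_factors_align_with_subscales(
            self, default_cohort):
        R = correlation_matrix(item_matrix(default_cohort))
        res = pca_factors(R)
        assert res.n_factors == 3
        a = res.factor_assignment
        # rules (time, coview, limits) / routines (meals, bedtime) /
        # conditions (onset, content) each load on a single distinct factor
        assert a[0] == a[1] == a[2]
        assert a[3] == a[4]
        assert a[5] == a[6]
        assert len({a[0], a[3], a[5]}) == 3


class TestCronbachAlpha:
    def test_duplicated_item_gives_alpha_one(self):
        x = np.random.default_rng(0).integers(0, 3, size=(100, 1)).astype(float)
        items = np.repeat(x, 7, axis=1)
        assert cronbach_alpha(items).cronbach_alpha == pytest.approx(1.0)

    def test_independent_items_alpha_near_zero(self):
        items = np.random.default_rng(1).integers(0, 3, (20000, 7)).astype(float)
        assert abs(cronbach_alpha(items).cronbach_alpha) < 0.05

    def test_anticorrelated_halves_can_go_negative(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(200, 1))
        # nearly perfectly anti-correlated pair: alpha is strongly negative
        items = np.hstack([x, -x + 0.05 * rng.normal(size=(200, 1))])
        assert cronbach_alpha(items).cronbach_alpha < -1

    def test_exactly_cancelling_items_are_degenerate(self):
        x = np.random.default_rng(3).normal(size=(50, 1))
        with pytest.raises(StatisticalError):
            cronbach_alpha(np.hstack([x, -x]))

    def test_variance_form_equals_covariance_form(self, default_cohort):
        items = item_matrix(default_cohort[:600])
        k = items.shape[1]
        C = np.cov(items, rowvar=False)
        mean_cov = (C.sum() - np.trace(C)) / (k * (k - 1))
        alpha_cov = k * mean_cov / (np.trace(C) / k + (k - 1) * mean_cov)
        assert cronbach_alpha(items).cronbach_alpha == pytest.approx(
            alpha_cov, rel=1e-10)

    def test_agrees_with_pingouin(self, default_cohort):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        items = item_matrix(default_cohort[:500])
        expected = pingouin.cronbach_alpha(data=pd.DataFrame(items))[0]
        assert cronbach_alpha(items).cronbach_alpha == pytest.approx(
            expected, rel=1e-9)

    def test_default_cohort_in_vicinity_of_study_value(self, default_cohort):
        alpha = cronbach_alpha(item_matrix(default_cohort)).cronbach_alpha
        assert 0.3 < alpha < 0.65  # study reported 0.49


class TestValidationBattery:
    def test_report_fields_consistent(self, default_cohort):
        rep = validation_battery(item_matrix(default_cohort[:400]))
        assert rep.bartlett_df == 21
        assert 0 <= rep.kmo_overall <= 1
        assert rep.loadings.shape == (7, rep.n_factors)
        d = rep.to_dict()
        assert set(d["factor_assignment"]) == set(rep.item_names)
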