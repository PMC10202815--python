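"""Pipeline-operation tests: couple identification, phenotype transforms,
screening, effective tests, corr-vs-MR comparison and convergence trends."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from couplemr import (
    CoupleModelParams,
    DegenerateInputError,
    InvalidArgumentError,
    MrFilters,
    ScreenFailureError,
    bin_couples,
    compare_corr_vs_mr,
    couple_correlation,
    couple_mr_from_cohort,
    effective_tests,
    identify_couples,
    inverse_normal_transform,
    screen_traits,
    simulate_couple_cohort,
    trend_test,
)


def _household(hid, persons):
    return [
        {
            "person_id": f"{hid}_{i}",
            "household_id": hid,
            "sex": sex,
            "related": rel,
            "relationship": code,
        }
        for i, (sex, rel, code) in enumerate(persons)
    ]


class TestIdentifyCouples:
    def test_rule_by_rule_enumeration(self):
        """Ten engineered households; exactly four pass all three rules."""
        rows = []
        rows += _household("h1", [("F", False, "partner"), ("M", False, "partner")])
        rows += _household("h2", [("M", False, "partner"), ("F", False, "partner")])
        rows += _household("h3", [("F", False, "partner"), ("M", False, "partner")])
        rows += _household("h4", [("M", False, "partner"), ("F", False, "partner")])
        rows += _household("h5", [("F", False, "partner")] * 3)  # size 3
        rows += _household("h6", [("F", False, "partner")])  # size 1
        rows += _household("h7", [("F", False, "partner"), ("F", False, "partner")])
        rows += _household("h8", [("M", True, "partner"), ("F", False, "partner")])
        rows += _household("h9", [("M", False, "partner"), ("F", False, "other")])
        rows += _household("h10", [("F", False, "other"), ("M", False, "other")])
        couples, excl = identify_couples(pd.DataFrame(rows))
        assert len(couples) == 4
        assert excl == {
            "household_size": 2,
            "same_sex": 1,
            "related": 1,
            "not_partner_coded": 2,
        }
        assert set(couples["household_id"]) == {"h1", "h2", "h3", "h4"}

    def test_duplicate_person_rejected(self):
        rows = _household("h1", [("F", False, "partner"), ("M", False, "partner")])
        rows[1]["person_id"] = rows[0]["person_id"]
        with pytest.raises(InvalidArgumentError):
            identify_couples(pd.DataFrame(rows))


class TestInverseNormalTransform:
    def test_blom_offset_for_three_values(self):
        out = inverse_normal_transform([10.0, 20.0, 30.0])
        expected = stats.norm.ppf((np.array([1, 2, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)
        assert expected[2] == pytest.approx(0.8694, abs=2e-4)

    def test_rank_preservation(self, rng):
        x = rng.exponential(2.0, 500)
        out = inverse_normal_transform(x)
        assert stats.spearmanr(x, out).statistic == pytest.approx(1.0)
        assert out.mean() == pytest.approx(0.0, abs=0.01)
        assert out.std() == pytest.approx(1.0, abs=0.05)

    def test_normal_input_near_fixed_point(self, rng):
        """Already-normal input is reproduced up to order-statistic noise
        (tails excluded, where extreme order statistics are volatile)."""
        x = rng.standard_normal(20_000)
        out = inverse_normal_transform(x)
        lo, hi = 500, 19_500
        diff = np.sort(out)[lo:hi] - np.sort(x)[lo:hi]
        assert np.max(np.abs(diff)) < 0.05
        assert np.corrcoef(x, out)[0, 1] > 0.999

    def test_ties_share_average_rank(self):
        out = inverse_normal_transform([1.0, 1.0, 2.0, 3.0])
        assert out[0] == out[1]

    def test_degenerate_inputs(self):
        with pytest.raises(DegenerateInputError):
            inverse_normal_transform([5.0, 5.0, 5.0])
        with pytest.raises(InvalidArgumentError):
            inverse_normal_transform([1.0, 2.0])


class TestCoupleCorrelation:
    def test_identity_and_null(self, rng):
        x = rng.standard_normal(1_000)
        r, se, rho = couple_correlation(x, x)
        assert r == pytest.approx(1.0)
        y = rng.standard_normal(10_000)
        r, _, _ = couple_correlation(rng.standard_normal(10_000), y)
        assert abs(r) < 0.03

    def test_direct_formula_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 3.5, 5.0, 0.5])
        y = np.array([0.8, 2.5, 3.0, 4.1, 4.0, 1.0])
        r, se, _ = couple_correlation(x, y)
        cx, cy = x - x.mean(), y - y.mean()
        oracle = float(cx @ cy / np.sqrt((cx @ cx) * (cy @ cy)))
        assert r == pytest.approx(oracle, abs=1e-12)
        assert se == pytest.approx(np.sqrt((1 - oracle**2) / 4), abs=1e-12)

    def test_pairwise_complete(self):
        x = np.array([1.0, 2.0, np.nan, 4.0, 5.0, 6.0])
        y = np.array([1.1, 2.2, 3.0, np.nan, 5.2, 6.1])
        r, _, _ = couple_correlation(x, y)
        assert r > 0.99

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateInputError):
            couple_correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


class TestScreenTraits:
    @pytest.mark.parametrize(
        "r,ivs,retained,reason",
        [
            (0.09, 20, False, "low_correlation"),
            (0.5, 4, False, "too_few_ivs"),
            (0.11, 5, True, "ok"),
            (0.1, 10, False, "low_correlation"),  # strict threshold
        ],
    )
    def test_boundaries(self, r, ivs, retained, reason):
        table = pd.DataFrame(
            {"trait": ["t"], "pearson_r": [r], "n_valid_ivs": [ivs]}
        )
        out = screen_traits(table)
        assert bool(out["retained"][0]) is retained
        assert out["reason"][0] == reason


class TestEffectiveTests:
    def test_identity_gives_m(self):
        assert effective_tests(np.eye(10)) == pytest.approx(10.0)

    def test_all_ones_gives_one(self):
        assert effective_tests(np.ones((7, 7))) == pytest.approx(1.0)

    def test_li_ji_eigen_oracle(self):
        corr = np.full((3, 3), 0.5)
        np.fill_diagonal(corr, 1.0)
        eig = np.round(np.linalg.eigvalsh(corr), 10)
        oracle = float(np.sum((eig >= 1) + (eig - np.floor(eig))))
        assert effective_tests(corr) == pytest.approx(oracle)
        assert oracle == pytest.approx(2.0)

    def test_non_psd_clipped_with_warning(self):
        corr = np.array([[1.0, 0.9, 0.1], [0.9, 1.0, 0.9], [0.1, 0.9, 1.0]])
        assert np.linalg.eigvalsh(corr).min() < 0  # genuinely non-PSD
        with pytest.warns(UserWarning):
            meff = effective_tests(corr)
        assert 1.0 <= meff <= 3.0


class TestCompareCorrVsMr:
    def test_equal_estimates(self):
        z, p = compare_corr_vs_mr(0.3, 0.01, 0.3, 0.02)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_direct_formula(self):
        z, p = compare_corr_vs_mr(0.3, 0.01, 0.1, 0.02)
        assert z == pytest.approx(0.2 / np.sqrt(0.0005), rel=1e-9)
        assert z == pytest.approx(8.944, abs=1e-3)

    def test_antisymmetry(self):
        z1, p1 = compare_corr_vs_mr(0.3, 0.01, 0.1, 0.02)
        z2, p2 = compare_corr_vs_mr(0.1, 0.02, 0.3, 0.01)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)


class TestBinCouples:
    def test_uniform_quantiles(self):
        codes, medians = bin_couples(np.arange(1.0, 101.0), 5)
        assert np.bincount(codes).tolist() == [20, 20, 20, 20, 20]
        assert np.all(np.diff(medians) > 0)

    def test_ties_stay_in_one_bin(self):
        values = np.concatenate([np.zeros(60), np.arange(1.0, 41.0)])
        codes, _ = bin_couples(values, 5)
        assert np.unique(codes[values == 0]).size == 1

    def test_too_few_distinct_values(self):
        with pytest.raises(InvalidArgumentError):
            bin_couples([1.0, 1.0, 2.0, 2.0], 5)


class TestTrendTest:
    def test_flat_estimates_give_zero_slope(self):
        res = trend_test([0.2, 0.2, 0.2], [0.1, 0.1, 0.1], [1.0, 2.0, 3.0])
        assert res.slope == pytest.approx(0.0, abs=1e-12)

    def test_exact_line(self):
        res = trend_test([0.1, 0.2, 0.3], [0.05, 0.05, 0.05], [1.0, 2.0, 3.0])
        assert res.slope == pytest.approx(0.1, abs=1e-10)

    def test_weighted_normal_equations_oracle(self, rng):
        y = rng.normal(0.2, 0.1, 5)
        s = rng.uniform(0.05, 0.3, 5)
        x = np.arange(5.0)
        res = trend_test(y, s, x)
        design = sm.add_constant(x)
        w = np.diag(1.0 / s)
        oracle = np.linalg.solve(design.T @ w @ design, design.T @ w @ y)
        assert res.slope == pytest.approx(oracle[1], abs=1e-10)

    def test_trend_recovery_from_drifting_assortment(self):
        """Bins simulated with linearly drifting direct assortment recover
        the drift slope within 2 se."""
        targets = np.array([0.30, 0.25, 0.20, 0.15, 0.10])
        rs, ses = [], []
        for b, r_target in enumerate(targets):
            params = CoupleModelParams(
                n_couples=4_000, n_snps=10, r_X=float(r_target), seed=100 + b
            )
            cohort = simulate_couple_cohort(params)
            r, se, _ = couple_correlation(
                cohort.trait("X", "index"), cohort.trait("X", "partner")
            )
            rs.append(r)
            ses.append(se)
        res = trend_test(rs, ses, np.arange(5.0))
        assert res.slope == pytest.approx(-0.05, abs=2 * res.slope_se)


class TestCoupleMrFromCohort:
    def test_self_mr_sanity(self, default_cohort):
        """Using the index's own phenotype as outcome recovers ~1."""
        est = couple_mr_from_cohort(
            default_cohort, "X", outcome_trait="X", filters=MrFilters(min_ivs=5)
        )
        # cross-partner estimate, but against the index itself:
        from couplemr.couple_pipeline import single_trait_couple_mr
        from couplemr.sim_cohort import emulate_gwas_summary

        exp = {
            s: emulate_gwas_summary(default_cohort, "X", "index", sex=s)
            for s in ("M", "F")
        }
        self_est = single_trait_couple_mr(exp, exp, filters=MrFilters())
        assert self_est.alpha == pytest.approx(1.0, abs=0.02)
        assert est.alpha == pytest.approx(0.2, abs=2 * est.se)

    def test_pure_environment_trait_refused(self):
        """With g=0 instruments explain nothing; the screen must refuse."""
        params = CoupleModelParams(
            n_couples=5_000, n_snps=30, g=0.0, e=1.0, r_X=0.2, seed=77
        )
        cohort = simulate_couple_cohort(params)
        with pytest.raises(ScreenFailureError):
            couple_mr_from_cohort(cohort, "X")
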