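"""Generative-model tests: genotypes, assortment, parental effects, GWAS
emulation, and agreement with the closed-form couple correlations."""

import numpy as np
import pytest

from couplemr import (
    BiasParams,
    CausalEdge,
    CoupleModelParams,
    InfeasibleModelError,
    InvalidArgumentError,
    TraitNetworkParams,
    TraitParams,
    assort_pairs,
    emulate_gwas_summary,
    expected_couple_correlations,
    simulate_couple_cohort,
    simulate_genotypes,
    simulate_trait_network,
)


class TestSimulateGenotypes:
    def test_hardy_weinberg_mean(self):
        geno = simulate_genotypes(10_000, 1, 0.5, seed=1)
        assert geno.mean() == pytest.approx(1.0, abs=0.03)
        assert set(np.unique(geno)) <= {0, 1, 2}

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_genotypes(100, 1, 0.0, seed=1)
        with pytest.raises(InvalidArgumentError):
            simulate_genotypes(0, 1, 0.5, seed=1)

    def test_columns_independent_without_ld(self):
        geno = simulate_genotypes(10_000, 2, (0.1, 0.4), seed=2)
        r = np.corrcoef(geno[:, 0], geno[:, 1])[0, 1]
        assert abs(r) < 0.03

    def test_ar1_ld_induces_adjacent_correlation(self):
        geno = simulate_genotypes(20_000, 4, 0.3, seed=3, ld_rho=0.8)
        r01 = np.corrcoef(geno[:, 0], geno[:, 1])[0, 1]
        r03 = np.corrcoef(geno[:, 0], geno[:, 3])[0, 1]
        assert r01 > 0.3
        assert r01 > r03


class TestAssortPairs:
    def test_perfect_target_is_rank_matching(self, rng):
        a = rng.normal(0, 1, 500)
        perm = assort_pairs(a, a, 1.0, seed=4)
        assert np.corrcoef(a, a[perm])[0, 1] == pytest.approx(1.0)
        # ranks align exactly
        assert np.array_equal(np.argsort(a), np.argsort(a[perm]))

    def test_zero_target_random_pairing(self, rng):
        a, b = rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000)
        perm = assort_pairs(a, b, 0.0, seed=5)
        assert abs(np.corrcoef(a, b[perm])[0, 1]) < 0.03

    def test_intermediate_target_recovered(self, rng):
        a, b = rng.normal(0, 1, 10_000), rng.normal(0, 1, 10_000)
        perm = assort_pairs(a, b, 0.5, seed=6)
        assert np.corrcoef(a, b[perm])[0, 1] == pytest.approx(0.5, abs=0.03)
        assert np.array_equal(np.sort(perm), np.arange(10_000))  # bijection

    def test_monotone_in_target(self, rng):
        a, b = rng.normal(0, 1, 5_000), rng.normal(0, 1, 5_000)
        realized = [
            np.corrcoef(a, b[assort_pairs(a, b, t, seed=7)])[0, 1]
            for t in (-0.5, 0.0, 0.3, 0.8)
        ]
        assert np.all(np.diff(realized) > 0)

    def test_invalid_target_rejected(self):
        with pytest.raises(InvalidArgumentError):
            assort_pairs([1.0, 2.0], [1.0, 2.0], 1.5)


class TestCoupleCohort:
    def test_direct_assortment_only_recovers_target(self, default_cohort):
        r = np.corrcoef(
            default_cohort.trait("X", "index"), default_cohort.trait("X", "partner")
        )[0, 1]
        assert r == pytest.approx(0.2, abs=3 / np.sqrt(20_000))

    def test_unit_variances(self, default_cohort, violation_cohort):
        """Environment and parental aggregates have unit variance; the
        trait variance is 1 + 2*g*e*c where c is the parental-effect
        induced genotype-environment correlation (1 when c = 0)."""
        for cohort in (default_cohort, violation_cohort):
            p = cohort.params
            c = (p.s_G + p.s_X * p.g) / np.sqrt(2)
            var_x = 1.0 + 2.0 * p.g * p.e * c
            assert cohort.trait("X", "index").var() == pytest.approx(var_x, abs=0.05)
            assert cohort.env("X", "index").var() == pytest.approx(1.0, abs=0.05)
            for comp in ("G_P", "E_P", "X_P"):
                par = cohort.parental["X"]["index"][comp]
                assert par.var() == pytest.approx(1.0, abs=0.05)

    def test_parental_transmission_near_inv_sqrt2(self, violation_cohort):
        g_par = violation_cohort.parental["X"]["index"]["G_P"]
        g_off = violation_cohort.score("X", "index")
        assert np.corrcoef(g_par, g_off)[0, 1] == pytest.approx(
            1 / np.sqrt(2), abs=0.02
        )

    def test_all_closed_form_correlations_jointly(self, violation_cohort):
        """The trait, environment and genotype cross-partner correlations
        and the within-person G-E correlation all match their closed
        forms simultaneously on one cohort."""
        p = violation_cohort.params
        bp = BiasParams(
            g=p.g, e=p.e, r_G=p.r_G, r_E=p.r_E, r_X=p.r_X,
            s_G=p.s_G, s_E=p.s_E, s_X=p.s_X,
        )
        exp_x, exp_e, exp_g = expected_couple_correlations(bp)
        tol = 3 / np.sqrt(p.n_couples)
        pairs = [
            (violation_cohort.trait("X", "index"), violation_cohort.trait("X", "partner"), exp_x),
            (violation_cohort.env("X", "index"), violation_cohort.env("X", "partner"), exp_e),
            (violation_cohort.score("X", "index"), violation_cohort.score("X", "partner"), exp_g),
        ]
        for a, b, expected in pairs:
            assert np.corrcoef(a, b)[0, 1] == pytest.approx(expected, abs=tol)
        c_expected = (p.s_G + p.s_X * p.g) / np.sqrt(2)
        c_realized = np.corrcoef(
            violation_cohort.score("X", "index"), violation_cohort.env("X", "index")
        )[0, 1]
        assert c_realized == pytest.approx(c_expected, abs=tol)

    def test_independence_case(self):
        params = CoupleModelParams(n_couples=10_000, n_snps=30, r_X=0.0, seed=21)
        cohort = simulate_couple_cohort(params)
        r = np.corrcoef(cohort.trait("X", "index"), cohort.trait("X", "partner"))[0, 1]
        assert abs(r) < 3 / np.sqrt(10_000)
        assert cohort.trait("X", "index").var() == pytest.approx(1.0, abs=0.05)

    def test_seed_reproducibility(self):
        params = CoupleModelParams(n_couples=2_000, n_snps=20, r_X=0.2, seed=33)
        a = simulate_couple_cohort(params)
        b = simulate_couple_cohort(params)
        np.testing.assert_array_equal(a.trait("X", "index"), b.trait("X", "index"))
        np.testing.assert_array_equal(
            a.genotype_matrix("X", "partner"), b.genotype_matrix("X", "partner")
        )

    def test_infeasible_targets_raise(self):
        # scalar couple-correlation check passes (0.9 <= 1) but the joint
        # cross-covariance has a singular value (1 + c)^2 * 0.9 > 1
        params = CoupleModelParams(
            n_couples=2_000, n_snps=20, r_X=0.0, r_E=0.9, r_G=0.9, s_G=0.3, seed=34
        )
        with pytest.raises(InfeasibleModelError):
            simulate_couple_cohort(params)
        with pytest.raises(InvalidArgumentError):
            CoupleModelParams(r_X=0.9, r_E=0.9, r_G=0.9)

    def test_opposite_sex_labels(self, default_cohort):
        assert np.all(default_cohort.sex["index"] != default_cohort.sex["partner"])


class TestTraitNetwork:
    def test_within_person_effect_recovered(self, exposure_assortment_cohort):
        x = exposure_assortment_cohort.trait("X", "index")
        y = exposure_assortment_cohort.trait("Y", "index")
        slope = np.polyfit(x, y, 1)[0]
        assert slope == pytest.approx(0.3, abs=0.02)

    def test_path_product_cross_correlation(self, exposure_assortment_cohort):
        """cor(X_i, Y_p) equals the product of the assortment and the
        within-person causal path: 0.2 * 0.3."""
        r = np.corrcoef(
            exposure_assortment_cohort.trait("X", "index"),
            exposure_assortment_cohort.trait("Y", "partner"),
        )[0, 1]
        assert r == pytest.approx(0.06, abs=3 / np.sqrt(50_000) + 0.005)

    def test_null_path_no_cross_correlation(self):
        params = TraitNetworkParams(
            n_couples=10_000,
            traits={
                "X": TraitParams(n_snps=30, r_assort=0.2),
                "Y": TraitParams(n_snps=30, r_assort=0.0),
            },
            edges=(),
            seed=41,
        )
        net = simulate_trait_network(params)
        r = np.corrcoef(net.trait("X", "index"), net.trait("Y", "partner"))[0, 1]
        assert abs(r) < 3 / np.sqrt(10_000)

    def test_confounder_induced_couple_correlation(self, confounder_cohort):
        """cor(X_i, X_p) = alpha_{y->x}^2 * couple effect = 0.25 * 0.4."""
        r = np.corrcoef(
            confounder_cohort.trait("X", "index"),
            confounder_cohort.trait("X", "partner"),
        )[0, 1]
        assert r == pytest.approx(0.1, abs=3 / np.sqrt(50_000) + 0.005)

    def test_cycle_detection(self):
        with pytest.raises(InvalidArgumentError):
            TraitNetworkParams(
                traits={"X": TraitParams(), "Y": TraitParams()},
                edges=(CausalEdge("X", "Y", 0.3), CausalEdge("Y", "X", 0.3)),
            ).topological_order()


class TestEmulateGwas:
    def test_per_snp_effect_matches_variance_share(self, default_cohort):
        """Equal-effect SNPs each explain h2/k of trait variance, so the
        standardized per-SNP effect is sqrt(0.2/50)."""
        stats_ = emulate_gwas_summary(default_cohort, "X", "index")
        expected = np.sqrt(0.2 / 50)
        assert stats_.beta.mean() == pytest.approx(expected, abs=0.005)

    def test_null_trait_type_one_error(self):
        params = CoupleModelParams(
            n_couples=10_000, n_snps=60, g=0.0, e=1.0, r_X=0.2, seed=55
        )
        cohort = simulate_couple_cohort(params)
        stats_ = emulate_gwas_summary(cohort, "X", "index")
        frac = np.mean(stats_.pval < 0.05)
        assert frac == pytest.approx(0.05, abs=0.08)

    def test_standard_error_large_sample_form(self, default_cohort):
        stats_ = emulate_gwas_summary(default_cohort, "X", "index")
        assert np.median(stats_.se) == pytest.approx(
            1 / np.sqrt(20_000), rel=0.05
        )

    def test_sex_stratification_splits_sample(self, default_cohort):
        m = emulate_gwas_summary(default_cohort, "X", "index", sex="M")
        f = emulate_gwas_summary(default_cohort, "X", "index", sex="F")
        assert m.n[0] + f.n[0] == default_cohort.n_couples

    def test_covariate_adjustment_removes_signal(self, default_cohort):
        """Adjusting the phenotype for the genetic score itself leaves no
        per-SNP association signal beyond chance."""
        cov = default_cohort.score("X", "index")[:, None]
        stats_ = emulate_gwas_summary(default_cohort, "X", "index", covariates=cov)
        assert np.mean(stats_.pval < 0.05) < 0.12
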