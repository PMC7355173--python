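"""Synthetic-cohort generator: marginals, LD structure, HWE, determinism."""

import numpy as np
import pytest
from scipy import stats

from gxescan import (
    EffectSpec,
    ExposureSpec,
    GeneSpec,
    SimConfig,
    simulate_cohort,
    simulate_exposures_covariates,
    simulate_genotypes,
    simulate_phenotype,
)
from gxescan.simulate import ConfigurationError


def _single_gene_config(n, n_snps=1, ld_rho=0.0, maf=(0.3, 0.3), seed=0):
    return SimConfig(
        n_individuals=n,
        genes=[GeneSpec("G1", n_snps, ld_rho, maf)],
        seed=seed,
    )


class TestGenotypes:
    def test_seeded_determinism_is_bit_identical(self):
        cfg = SimConfig(n_individuals=100, genes=[GeneSpec("G1", 4, 0.5)], seed=7)
        g1, ids1, map1 = simulate_genotypes(cfg)
        g2, ids2, map2 = simulate_genotypes(cfg)
        assert ids1 == ids2
        assert (g1 == g2).all()
        assert map1.equals(map2)

    def test_allele_frequency_matches_binomial_oracle(self):
        # 2n haploid draws at MAF 0.3: SE = sqrt(p(1-p)/2n)
        n = 50_000
        g, _, _ = simulate_genotypes(_single_gene_config(n, seed=3))
        freq = g[:, 0].sum() / (2 * n)
        se = np.sqrt(0.3 * 0.7 / (2 * n))
        assert abs(freq - 0.3) < 4 * se

    def test_ld_rho_orders_adjacent_dosage_correlation(self):
        n = 50_000

        def mean_adjacent_r(rho):
            cfg = _single_gene_config(n, n_snps=5, ld_rho=rho, seed=11)
            g, _, _ = simulate_genotypes(cfg)
            rs = [np.corrcoef(g[:, j], g[:, j + 1])[0, 1] for j in range(4)]
            return np.mean(rs)

        assert mean_adjacent_r(0.9) > mean_adjacent_r(0.1)

    def test_dosages_satisfy_hwe_by_construction(self):
        # chi-square HWE at alpha=0.001 should pass for >=99% of SNPs
        from gxescan import hwe_test

        n = 50_000
        failures = total = 0
        for seed in range(3):
            cfg = SimConfig(
                n_individuals=n,
                genes=[GeneSpec(f"G{i}", 5, 0.5) for i in range(8)],
                seed=seed,
            )
            g, _, _ = simulate_genotypes(cfg)
            for j in range(g.shape[1]):
                d = g[:, j]
                p = hwe_test(
                    int((d == 0).sum()), int((d == 1).sum()), int((d == 2).sum())
                )
                failures += p < 0.001
                total += 1
        assert failures / total <= 0.01

    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            SimConfig(n_individuals=0).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(genes=[GeneSpec("G1", 0)]).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(genes=[GeneSpec("G1", 2, maf_range=(0.0, 0.5))]).validate()
        with pytest.raises(ConfigurationError):
            SimConfig(genes=[GeneSpec("G1", 2, ld_rho=1.5)]).validate()

    def test_missingness_injector(self):
        cfg = SimConfig(
            n_individuals=2000, genes=[GeneSpec("G1", 5, 0.3)],
            missing_rate=0.05, seed=5,
        )
        g, _, _ = simulate_genotypes(cfg)
        frac = np.isnan(g).mean()
        assert 0.03 < frac < 0.07


class TestExposuresCovariates:
    def test_right_skewed_exposure_has_floor_mass_and_skew(self):
        cfg = SimConfig(
            n_individuals=10_000,
            genes=[GeneSpec("G1", 2)],
            exposures=[ExposureSpec("hp", "right_skewed")],
            seed=9,
        )
        tab = simulate_exposures_covariates(cfg)
        hp = tab["hp"].to_numpy()
        assert stats.skew(hp) > 1
        assert (hp == 1.0).mean() >= 0.5
        assert np.median(hp) == 1.0  # median can coincide with the minimum

    def test_degenerate_bounded_normal_is_constant(self):
        cfg = SimConfig(
            n_individuals=50,
            genes=[GeneSpec("G1", 2)],
            exposures=[ExposureSpec("e", "bounded_normal", mean=3.0, sd=0.0)],
            seed=1,
        )
        tab = simulate_exposures_covariates(cfg)
        assert (tab["e"] == 3.0).all()

    def test_exposures_stay_on_scale(self):
        cfg = SimConfig(
            n_individuals=5000,
            genes=[GeneSpec("G1", 2)],
            exposures=[
                ExposureSpec("wide", "bounded_normal", mean=1.0, sd=5.0),
                ExposureSpec("hp", "right_skewed", gamma_scale=3.0),
            ],
            seed=2,
        )
        tab = simulate_exposures_covariates(cfg)
        for col in ("wide", "hp"):
            assert tab[col].between(1.0, 5.0).all()

    def test_sex_fraction_matches_binomial_oracle(self):
        n = 10_000
        cfg = SimConfig(n_individuals=n, genes=[GeneSpec("G1", 2)], seed=4)
        tab = simulate_exposures_covariates(cfg)
        se = np.sqrt(0.505 * 0.495 / n)
        assert abs(tab["sex"].mean() - 0.505) < 4 * se

    def test_age_moments(self):
        n = 20_000
        cfg = SimConfig(n_individuals=n, genes=[GeneSpec("G1", 2)], seed=6)
        tab = simulate_exposures_covariates(cfg)
        assert abs(tab["age"].mean() - 13.78) < 4 * 0.92 / np.sqrt(n)
        assert abs(tab["age"].std() - 0.92) < 0.05


class TestPhenotype:
    def test_null_phenotype_uncorrelated_with_gxe_products(self):
        n = 5000
        cfg = SimConfig(
            n_individuals=n, genes=[GeneSpec("G1", 3, 0.5)], seed=8,
            effect=EffectSpec(noise_sd=1.0),
        )
        cohort = simulate_cohort(cfg)
        y = cohort.pheno["symptom_score"].to_numpy()
        e = cohort.pheno["harsh_punitive_control"].to_numpy()
        for j in range(3):
            ge = cohort.genotypes[:, j] * e
            r = np.corrcoef(y, ge)[0, 1]
            assert abs(r) < 4 / np.sqrt(n)

    def test_noiseless_interaction_recovered_by_ols(self):
        # tiny noise, single-SNP gene: full-design regression recovers beta_gxe
        n = 2000
        effect = EffectSpec(
            target_gene="G1", exposure="harsh_punitive_control",
            beta_gxe=0.5, beta_g=0.2, beta_e=0.1,
            beta_age=0.05, beta_sex=0.3, noise_sd=1e-10,
        )
        cfg = SimConfig(
            n_individuals=n, genes=[GeneSpec("G1", 1, 0.0)], seed=10,
            effect=effect,
        )
        cohort = simulate_cohort(cfg)
        g = cohort.genotypes[:, 0]
        e = cohort.pheno["harsh_punitive_control"].to_numpy()
        X = np.column_stack(
            [
                np.ones(n), g, e, g * e,
                cohort.pheno["age"].to_numpy(),
                cohort.pheno["sex"].to_numpy(),
            ]
        )
        beta = np.linalg.lstsq(X, cohort.pheno["symptom_score"], rcond=None)[0]
        assert beta[3] == pytest.approx(0.5, abs=1e-6)

    def test_same_seed_same_phenotype(self):
        cfg = SimConfig(n_individuals=200, genes=[GeneSpec("G1", 2)], seed=3)
        c1 = simulate_cohort(cfg)
        c2 = simulate_cohort(cfg)
        assert (
            c1.pheno["symptom_score"].to_numpy()
            == c2.pheno["symptom_score"].to_numpy()
        ).all()

    def test_misaligned_inputs_raise(self):
        from gxescan.simulate import AlignmentError

        cfg = SimConfig(n_individuals=50, genes=[GeneSpec("G1", 2)], seed=0)
        g, ids, gmap = simulate_genotypes(cfg)
        cov = simulate_exposures_covariates(
            SimConfig(n_individuals=60, genes=[GeneSpec("G1", 2)], seed=0)
        )
        with pytest.raises(AlignmentError):
            simulate_phenotype(g, ids, gmap, cov, EffectSpec(), seed=0)
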