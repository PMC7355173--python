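"""Per-SNP interaction scan: design construction, OLS numerics, null
calibration and invariances."""

import numpy as np
import pytest
from scipy import stats

from gxescan import (
    GeneSpec,
    ScanModelSpec,
    SimConfig,
    build_design,
    fit_snp_interaction,
    scan_all,
    simulate_cohort,
)
from gxescan.data import CohortData


def _vectors(n=40, seed=0):
    rng = np.random.default_rng(seed)
    g = rng.binomial(2, 0.3, size=n).astype(float)
    e = rng.uniform(1, 5, size=n)
    covs = {
        "age": rng.normal(13.8, 0.9, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
    }
    return g, e, covs


class TestBuildDesign:
    def test_column_count_without_keller_terms(self):
        g, e, covs = _vectors()
        spec = ScanModelSpec("hp", keller_terms=False, min_nonmissing=10)
        X, names, mask = build_design(g, e, covs, spec)
        assert X.shape[1] == 6
        assert names == ["intercept", "g", "e", "g:e", "age", "sex"]

    def test_column_count_with_keller_terms(self):
        g, e, covs = _vectors()
        spec = ScanModelSpec("hp", keller_terms=True, min_nonmissing=10)
        X, names, _ = build_design(g, e, covs, spec)
        assert X.shape[1] == 10  # 6 + covariate-by-g and covariate-by-e products

    def test_complete_case_rows_dropped(self):
        g, e, covs = _vectors()
        g[:5] = np.nan
        spec = ScanModelSpec("hp", min_nonmissing=10)
        X, _, mask = build_design(g, e, covs, spec)
        assert X.shape[0] == 35 and mask.sum() == 35

    def test_all_missing_genotype_is_degenerate(self):
        g, e, covs = _vectors()
        g[:] = np.nan
        spec = ScanModelSpec("hp", min_nonmissing=10)
        with pytest.raises(ValueError, match="complete cases"):
            build_design(g, e, covs, spec)


class TestFitSnpInteraction:
    def test_noiseless_recovery_of_interaction_coefficient(self):
        g, e, covs = _vectors(n=60, seed=1)
        spec = ScanModelSpec("hp", min_nonmissing=10)
        X, names, _ = build_design(g, e, covs, spec)
        beta_true = np.zeros(X.shape[1])
        beta_true[names.index("g:e")] = 0.7
        beta_true[0] = 1.0
        y = X @ beta_true
        res = fit_snp_interaction(y, X, names, "s", "G")
        assert res.beta_gxe == pytest.approx(0.7, abs=1e-8)
        assert res.p < 1e-50  # exact fit: p underflows toward 0

    def test_constant_genotype_is_degenerate(self):
        g, e, covs = _vectors()
        g[:] = 1.0
        spec = ScanModelSpec("hp", keller_terms=False, min_nonmissing=10)
        X, names, _ = build_design(g, e, covs, spec)
        res = fit_snp_interaction(np.random.default_rng(0).normal(size=40), X,
                                  names)
        assert res.status == "skipped_degenerate"

    def test_matches_normal_equations_and_t_distribution_oracle(self):
        # independent oracle: explicit normal equations + survival function
        g, e, covs = _vectors(n=40, seed=7)
        rng = np.random.default_rng(8)
        spec = ScanModelSpec("hp", min_nonmissing=10)
        X, names, _ = build_design(g, e, covs, spec)
        y = rng.normal(size=40)
        j = names.index("g:e")
        xtx_inv = np.linalg.inv(X.T @ X)
        beta = xtx_inv @ X.T @ y
        resid = y - X @ beta
        df = X.shape[0] - X.shape[1]
        se = np.sqrt(resid @ resid / df * xtx_inv[j, j])
        t = beta[j] / se
        p = 2 * stats.t.sf(abs(t), df)
        res = fit_snp_interaction(y, X, names)
        assert res.beta_gxe == pytest.approx(beta[j], rel=1e-8)
        assert res.se == pytest.approx(se, rel=1e-8)
        assert res.t == pytest.approx(t, rel=1e-8)
        assert res.p == pytest.approx(p, rel=1e-8)
        assert res.t == pytest.approx(res.beta_gxe / res.se, rel=1e-10)

    def test_matches_statsmodels_ols(self):
        sm = pytest.importorskip("statsmodels.api")
        g, e, covs = _vectors(n=50, seed=3)
        spec = ScanModelSpec("hp", min_nonmissing=10)
        X, names, _ = build_design(g, e, covs, spec)
        y = np.random.default_rng(4).normal(size=50)
        fit = sm.OLS(y, X).fit()
        j = names.index("g:e")
        res = fit_snp_interaction(y, X, names)
        assert res.beta_gxe == pytest.approx(fit.params[j], rel=1e-8)
        assert res.p == pytest.approx(fit.pvalues[j], rel=1e-8)


class TestScanAll:
    def test_one_result_per_snp_in_stable_order(self, null_cohort, hp_spec):
        results = scan_all(null_cohort, hp_spec)
        assert [r.snp_id for r in results] == null_cohort.snp_ids

    def test_null_interaction_pvalues_are_uniform(self):
        # 2,000 independent SNPs under the null: KS distance < 0.05
        config = SimConfig(
            n_individuals=300,
            genes=[GeneSpec(f"G{i}", 2, 0.0) for i in range(1000)],
            seed=17,
        )
        cohort = simulate_cohort(config)
        results = scan_all(cohort, ScanModelSpec("harsh_punitive_control"))
        p = np.array([r.p for r in results if r.status == "ok"])
        assert len(p) > 1900
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 0.05
        for alpha in (0.05, 0.01):
            tol = 3 * np.sqrt(alpha * (1 - alpha) / len(p))
            assert abs((p < alpha).mean() - alpha) < tol

    def test_joint_sample_permutation_leaves_p_unchanged(self, null_cohort,
                                                         hp_spec):
        rng = np.random.default_rng(5)
        order = rng.permutation(null_cohort.n_samples)
        permuted = CohortData(
            genotypes=null_cohort.genotypes[order],
            snp_ids=list(null_cohort.snp_ids),
            sample_ids=[null_cohort.sample_ids[i] for i in order],
            gene_map=null_cohort.gene_map.copy(),
            pheno=null_cohort.pheno.iloc[order],
        )
        p0 = [r.p for r in scan_all(null_cohort, hp_spec)]
        p1 = [r.p for r in scan_all(permuted, hp_spec)]
        np.testing.assert_allclose(p0, p1, rtol=1e-9)

    def test_affine_exposure_rescaling_preserves_p(self, null_cohort, hp_spec):
        e = null_cohort.aligned_pheno()["harsh_punitive_control"].to_numpy()
        rescaled = null_cohort.with_exposure(
            "harsh_punitive_control", 10.0 * e - 3.0
        )
        r0 = scan_all(null_cohort, hp_spec)
        r1 = scan_all(rescaled, hp_spec)
        np.testing.assert_allclose(
            [r.p for r in r0], [r.p for r in r1], rtol=1e-7
        )
        # interaction coefficient rescales by 1/10
        np.testing.assert_allclose(
            [r.beta_gxe / 10.0 for r in r0],
            [r.beta_gxe for r in r1],
            rtol=1e-7, atol=1e-12,
        )
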