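"""Brown pooling: covariance approximation, limits, filters, calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from gxescan import (
    LDMatrix,
    SnpInteractionResult,
    bonferroni_threshold,
    brown_pool,
    fisher_pool,
    pairwise_covariance,
    pool_all_genes,
)


class TestPairwiseCovariance:
    @pytest.mark.parametrize(
        "rho, expected",
        [
            (0.0, 0.0),
            (1.0, 4.0),   # 3.263 + 0.710 + 0.027, clamped endpoint
            (-1.0, 4.0),  # sign-symmetric under the default |r| mapping
        ],
    )
    def test_known_values(self, rho, expected):
        assert pairwise_covariance(rho) == pytest.approx(expected)

    def test_polynomial_value_at_half(self):
        expected = 3.263 * 0.5 + 0.710 * 0.25 + 0.027 * 0.125
        assert pairwise_covariance(0.5) == pytest.approx(expected, rel=1e-12)

    def test_out_of_domain_rejected(self):
        with pytest.raises(ValueError):
            pairwise_covariance(1.1)

    @given(st.floats(-1, 1))
    @settings(deadline=None, max_examples=50)
    def test_bounded_and_sign_symmetric(self, rho):
        cov = pairwise_covariance(rho)
        assert 0.0 <= cov <= 4.0
        assert cov == pairwise_covariance(-rho)

    def test_signed_variant_floors_negative_correlations_at_zero(self):
        assert pairwise_covariance(-0.5, signed=True) == 0.0


class TestBrownPool:
    def test_single_test_passes_through(self):
        res = brown_pool(np.array([0.37]), LDMatrix.identity(["s1"]))
        assert res.p_pooled == pytest.approx(0.37, rel=1e-12)
        assert res.c == pytest.approx(1.0) and res.f == pytest.approx(2.0)

    def test_identity_ld_reduces_to_fisher(self):
        p = np.array([0.1, 0.2, 0.3])
        res = brown_pool(p, LDMatrix.identity(["a", "b", "c"]))
        T = -2 * np.log(p).sum()
        assert res.T == pytest.approx(10.2320, abs=1e-4)
        assert res.c == pytest.approx(1.0) and res.f == pytest.approx(6.0)
        assert res.p_pooled == pytest.approx(stats.chi2.sf(T, 6), rel=1e-12)
        assert res.p_pooled == pytest.approx(0.11522, abs=1e-4)

    @given(
        st.integers(1, 8),
        st.randoms(use_true_random=False),
    )
    @settings(deadline=None, max_examples=100)
    def test_fisher_limit_for_random_p_vectors(self, k, rnd):
        p = np.array([rnd.uniform(1e-12, 1.0) for _ in range(k)])
        ids = [f"s{i}" for i in range(k)]
        res = brown_pool(p, LDMatrix.identity(ids))
        assert res.p_pooled == pytest.approx(fisher_pool(p), abs=1e-12)

    def test_perfect_ld_equal_p_collapses_to_single_test(self):
        # all pairwise r=1, all p equal: Var=4k^2, c=k, f=2, pooled = p0
        for k in (2, 3, 6):
            p0 = 0.037
            ld = LDMatrix([f"s{i}" for i in range(k)], np.ones((k, k)))
            res = brown_pool(np.full(k, p0), ld)
            assert res.c == pytest.approx(k) and res.f == pytest.approx(2.0)
            assert res.p_pooled == pytest.approx(p0, rel=1e-10)

    def test_pooled_p_monotone_in_T(self):
        ld = LDMatrix.identity(["a", "b"])
        p_small = brown_pool(np.array([0.01, 0.02]), ld).p_pooled
        p_large = brown_pool(np.array([0.5, 0.6]), ld).p_pooled
        assert p_small < p_large

    def test_scale_c_nondecreasing_in_ld_strength(self):
        p = np.array([0.1, 0.2, 0.3])
        cs = []
        for r in (0.0, 0.3, 0.6, 0.9):
            m = np.full((3, 3), r)
            np.fill_diagonal(m, 1.0)
            cs.append(brown_pool(p, LDMatrix(["a", "b", "c"], m)).c)
        assert all(c1 >= c0 for c0, c1 in zip(cs, cs[1:]))

    def test_invalid_pvalues_rejected(self):
        ld = LDMatrix.identity(["a"])
        with pytest.raises(ValueError):
            brown_pool(np.array([0.0]), ld)
        with pytest.raises(ValueError):
            brown_pool(np.array([]), LDMatrix(snp_ids=[], r=np.empty((0, 0))))

    def test_null_calibration_against_brute_force_monte_carlo(self):
        # 3-SNP gene with known latent correlation: simulate the null of
        # T by drawing correlated z-scores, and check the analytic pooled
        # p rejects at ~nominal 0.05
        rho = 0.6
        k = 3
        corr = rho ** np.abs(np.subtract.outer(np.arange(k), np.arange(k)))
        ld = LDMatrix([f"s{i}" for i in range(k)], corr)
        rng = np.random.default_rng(99)
        L = np.linalg.cholesky(corr)
        z = rng.standard_normal((100_000, k)) @ L.T
        p_snp = 2 * stats.norm.sf(np.abs(z))
        pooled = np.array(
            [brown_pool(row, ld).p_pooled for row in p_snp[:20_000]]
        )
        rejection = (pooled < 0.05).mean()
        assert abs(rejection - 0.05) < 0.015


class TestPoolAllGenes:
    @staticmethod
    def _snp(snp, gene, p, status="ok"):
        return SnpInteractionResult(snp, gene, 100, 0.1, 0.05, 2.0, p,
                                    status=status)

    def test_min_snp_filter_and_order(self):
        results = [
            self._snp("a1", "gA", 0.2),
            self._snp("b1", "gB", 0.1),
            self._snp("b2", "gB", 0.3),
            self._snp("c1", "gC", 0.2),
            self._snp("c2", "gC", 0.4),
            self._snp("c3", "gC", 0.6),
        ]
        ld = {
            "gA": LDMatrix.identity(["a1"]),
            "gB": LDMatrix.identity(["b1", "b2"]),
            "gC": LDMatrix.identity(["c1", "c2", "c3"]),
        }
        pooled = pool_all_genes(results, ld, min_snps=2)
        assert [g.gene_id for g in pooled] == ["gB", "gC"]

    def test_degenerate_snps_reduce_k_and_subset_ld(self):
        results = [
            self._snp("c1", "gC", 0.2),
            self._snp("c2", "gC", np.nan, status="skipped_degenerate"),
            self._snp("c3", "gC", 0.6),
        ]
        r = np.array([[1.0, 0.5, 0.3], [0.5, 1.0, 0.4], [0.3, 0.4, 1.0]])
        ld = {"gC": LDMatrix(["c1", "c2", "c3"], r)}
        (g,) = pool_all_genes(results, ld, min_snps=2)
        assert g.k == 2
        expected = brown_pool(
            np.array([0.2, 0.6]),
            LDMatrix(["c1", "c3"], np.array([[1.0, 0.3], [0.3, 1.0]])),
        )
        assert g.p_pooled == pytest.approx(expected.p_pooled, rel=1e-12)

    def test_missing_ld_matrix_is_consistency_error(self):
        results = [self._snp("a1", "gA", 0.2), self._snp("a2", "gA", 0.4)]
        with pytest.raises(KeyError, match="gA"):
            pool_all_genes(results, {}, min_snps=2)


@pytest.mark.parametrize(
    "n, alpha, expected",
    [(274, 0.05, 0.05 / 274), (10, 0.05, 0.005), (1, 0.05, 0.05)],
)
def test_bonferroni_threshold(n, alpha, expected):
    assert bonferroni_threshold(n, alpha) == pytest.approx(expected, rel=1e-12)


def test_bonferroni_rounds_to_printed_two_significant_digits():
    thr = bonferroni_threshold(274, 0.05)
    assert float(f"{thr:.1e}") == 1.8e-4
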