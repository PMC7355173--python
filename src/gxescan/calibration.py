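"""Seeded calibration studies for the whole pipeline.

Each function runs the analysis end to end on synthetic cohorts and
measures one operating characteristic: family-wise/type-I error under
the complete null, genomic-control inflation, agreement between the
analytic pooled p-value and its own permutation null, equivalence with
Fisher's method in the independence limit, and power/ranking of an
injected G-by-E signal.  They back both the test suite and the
reproduction script; every study is deterministic given its seed.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .combine import bonferroni_threshold, brown_pool, fisher_pool, pool_all_genes
from .data import LDMatrix
from .ld import gene_ld_blocks
from .qc import apply_qc
from .scan import ScanModelSpec, scan_all
from .simulate import (
    EffectSpec,
    GeneSpec,
    SimConfig,
    default_genes,
    gxe_beta_for_power,
    simulate_cohort,
)
from .validate import genomic_control_lambda, permutation_test

__all__ = [
    "derive_seed",
    "null_calibration_study",
    "permutation_consistency_study",
    "signal_recovery_study",
    "fisher_equivalence_study",
    "perfect_ld_study",
]

_MOD = 2**31 - 1


def derive_seed(base_seed: int, stream: int) -> int:
    """Independent 31-bit child seed for stream ``stream``."""
    return (base_seed * 1_000_003 + stream * 7919 + 1) % _MOD


def null_calibration_study(
    n_seeds: int = 100,
    n_genes: int = 200,
    n_individuals: int = 948,
    base_seed: int = 0,
    exposure: str = "harsh_punitive_control",
    alpha: float = 0.05,
) -> dict:
    """Gene-level type-I error and lambda over replicate null cohorts.

    Each replicate simulates a cohort with no G-by-E effect, runs
    QC -> scan -> LD -> Brown pooling, and records the gene p-values and
    the genomic-control lambda.  Returns the pooled empirical type-I
    error at ``alpha`` and the per-replicate lambdas.
    """
    spec = ScanModelSpec(exposure=exposure)
    pvals: list[np.ndarray] = []
    lambdas: list[float] = []
    for i in range(n_seeds):
        config = SimConfig(
            n_individuals=n_individuals,
            genes=default_genes(n_genes),
            seed=derive_seed(base_seed, i),
        )
        cohort, _ = apply_qc(simulate_cohort(config))
        genes = pool_all_genes(
            scan_all(cohort, spec), gene_ld_blocks(cohort)
        )
        p = np.array([g.p_pooled for g in genes])
        pvals.append(p)
        lambdas.append(genomic_control_lambda(p))
    all_p = np.concatenate(pvals)
    lam = np.array(lambdas)
    return {
        "type_i_error": float((all_p < alpha).mean()),
        "n_gene_pvalues": int(all_p.size),
        "lambdas": lam,
        "lambda_median": float(np.median(lam)),
        "lambda_in_band_frac": float(((lam >= 0.9) & (lam <= 1.1)).mean()),
    }


def permutation_consistency_study(
    n_genes: int = 80,
    snps_per_gene: int = 3,
    n_individuals: int = 948,
    n_perm: int = 1000,
    base_seed: int = 0,
    exposure: str = "harsh_punitive_control",
) -> dict:
    """Spearman agreement of analytic and permutation gene p-values.

    Uses an independent-SNP null cohort (LD rho = 0) so the analytic
    pooled p-value has no approximation error from the LD adjustment.
    """
    config = SimConfig(
        n_individuals=n_individuals,
        genes=[GeneSpec(f"G{i:04d}", snps_per_gene, 0.0) for i in range(n_genes)],
        seed=derive_seed(base_seed, 1000),
    )
    cohort, _ = apply_qc(simulate_cohort(config))
    spec = ScanModelSpec(exposure=exposure)
    genes, perms = permutation_test(
        cohort, spec, gene_ld_blocks(cohort),
        n_perm=n_perm, strategy="phenotype",
        seed=derive_seed(base_seed, 1001),
    )
    analytic = np.array([g.p_pooled for g in genes])
    empirical = np.array([p.p_empirical for p in perms])
    rho = float(stats.spearmanr(analytic, empirical).statistic)
    return {"spearman": rho, "n_genes": len(genes), "n_perm": n_perm}


def signal_recovery_study(
    n_seeds: int = 50,
    n_genes: int = 50,
    n_individuals: int = 948,
    target_snps: int = 4,
    power: float = 0.8,
    base_seed: int = 0,
    exposure: str = "harsh_punitive_control",
    alpha: float = 0.05,
) -> dict:
    """Recovery of one injected G-by-E gene among null genes.

    The interaction coefficient is calibrated so a single SNP carrying
    it alone would be detected with ~``power`` at ``alpha`` and n
    individuals; the target gene carries it on all its SNPs.  Measures
    how often the target attains the smallest pooled p-value and how
    often it is Bonferroni-significant.
    """
    genes = [GeneSpec("TARGET", target_snps, 0.5)] + default_genes(n_genes - 1)
    probe = SimConfig(n_individuals=n_individuals, genes=genes)
    beta = gxe_beta_for_power(
        probe, exposure, power=power, alpha=alpha,
        seed=derive_seed(base_seed, 2000),
    )
    spec = ScanModelSpec(exposure=exposure)
    top = significant = 0
    for i in range(n_seeds):
        config = SimConfig(
            n_individuals=n_individuals,
            genes=genes,
            effect=EffectSpec(
                target_gene="TARGET", exposure=exposure, beta_gxe=beta
            ),
            seed=derive_seed(base_seed, 3000 + i),
        )
        cohort, _ = apply_qc(simulate_cohort(config))
        pooled = pool_all_genes(scan_all(cohort, spec), gene_ld_blocks(cohort))
        p = np.array([g.p_pooled for g in pooled])
        ids = [g.gene_id for g in pooled]
        j = ids.index("TARGET")
        top += int(np.argmin(p) == j)
        significant += int(p[j] < bonferroni_threshold(len(pooled), alpha))
    return {
        "beta_gxe": float(beta),
        "top_rank_frac": top / n_seeds,
        "significant_frac": significant / n_seeds,
        "n_seeds": n_seeds,
    }


def fisher_equivalence_study(n_cases: int = 1000, base_seed: int = 0) -> dict:
    """Max |Brown(identity LD) - Fisher| over random (k, p-vector) cases."""
    rng = np.random.default_rng(derive_seed(base_seed, 4000))
    max_diff = 0.0
    for _ in range(n_cases):
        k = int(rng.integers(1, 11))
        p = rng.uniform(1e-12, 1.0, size=k)
        ld = LDMatrix.identity([f"s{i}" for i in range(k)])
        diff = abs(brown_pool(p, ld).p_pooled - fisher_pool(p))
        max_diff = max(max_diff, diff)
    return {"max_abs_diff": max_diff, "n_cases": n_cases}


def perfect_ld_study() -> dict:
    """Max |pooled p - p0| when k equal p-values share pairwise r = 1."""
    max_dev = 0.0
    for k in (2, 3, 5, 8, 12):
        for p0 in (1e-6, 1e-3, 0.037, 0.37, 0.9, 1.0):
            ld = LDMatrix([f"s{i}" for i in range(k)], np.ones((k, k)))
            res = brown_pool(np.full(k, p0), ld)
            max_dev = max(max_dev, abs(res.p_pooled - p0))
    return {"max_abs_dev": max_dev}
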