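"""Gene-level pooling of dependent SNP p-values by Brown's method.

Fisher's statistic T = -2 * sum(ln p_i) is chi-square with 2k df only
when the k tests are independent.  SNPs within a gene are correlated
through linkage disequilibrium, so T is treated as a scaled chi-square
c * chi2_f with moments matched to the dependent case:

    E[T]   = 2k
    Var[T] = 4k + 2 * sum_{i<j} cov(-2 ln p_i, -2 ln p_j)
    c = Var / (2 E),   f = 2 E^2 / Var

The pairwise covariance is the cubic Kost-McDermott approximation in
the correlation of the underlying test statistics, proxied here by the
dosage LD:  cov(rho) = 3.263*rho + 0.710*rho^2 + 0.027*rho^3, clamped
to [0, 4] (4 is the theoretical maximum for chi-square-2 margins).  By
default rho enters as |r| because the two-sided p-value dependence is
symmetric in the sign of the statistic correlation; the signed variant
is available for comparison with other implementations.

With an identity LD matrix the scale is 1 and f = 2k: Brown's method
reduces exactly to Fisher's.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import LDMatrix
from .scan import STATUS_OK, SnpInteractionResult

__all__ = [
    "GeneResult",
    "pairwise_covariance",
    "brown_pool",
    "fisher_pool",
    "pool_all_genes",
    "bonferroni_threshold",
    "mark_significant",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

# Kost & McDermott cubic approximation to cov(-2 ln p_i, -2 ln p_j)
_KM_COEFFS = (3.263, 0.710, 0.027)
#: covariance of two identical chi-square_2 variables — the admissible maximum
_COV_MAX = 4.0


@dataclass
class GeneResult:
    """Pooled interaction evidence for one gene.

    ``T`` is Fisher's statistic over the gene's usable SNPs, ``c`` and
    ``f`` the moment-matched scale and (possibly non-integer) degrees of
    freedom, ``p_pooled`` the upper tail of the scaled chi-square at T.
    """

    gene_id: str
    k: int
    T: float
    c: float
    f: float
    p_pooled: float
    significant: bool | None = None


def pairwise_covariance(rho: float, signed: bool = False) -> float:
    """Approximate cov(-2 ln p_i, -2 ln p_j) for statistic correlation rho.

    Cubic polynomial in |rho| (or signed rho when ``signed``), clamped
    to [0, 4].  |rho| beyond 1 + 1e-9 is a domain error.
    """
    if abs(rho) > 1 + 1e-9:
        raise ValueError(f"correlation {rho} outside [-1, 1]")
    x = float(np.clip(rho if signed else abs(rho), -1.0, 1.0))
    a1, a2, a3 = _KM_COEFFS
    cov = a1 * x + a2 * x * x + a3 * x**3
    return float(min(max(cov, 0.0), _COV_MAX))


def brown_pool(
    p_values: np.ndarray, ld: LDMatrix, signed: bool = False
) -> GeneResult:
    """Pool one gene's SNP p-values with LD-adjusted Brown's method.

    ``p_values`` must be in (0, 1] and aligned with ``ld``; returns the
    pooled statistic, scale, effective df and pooled p-value.  The
    gene_id on the result is empty; callers fill it in.
    """
    p = np.asarray(p_values, dtype=float)
    k = p.size
    if k == 0:
        raise ValueError("no p-values to pool")
    if k != ld.k:
        raise ValueError(f"{k} p-values but {ld.k}x{ld.k} LD matrix")
    if np.any(p <= 0.0) or np.any(p > 1.0):
        raise ValueError("p-values must lie in (0, 1]")
    T = float(-2.0 * np.log(p).sum())
    mean = 2.0 * k
    var = 4.0 * k
    iu = np.triu_indices(k, 1)
    for rho in ld.r[iu]:
        var += 2.0 * pairwise_covariance(float(rho), signed=signed)
    c = var / (2.0 * mean)
    f = 2.0 * mean * mean / var
    # scaled chi-square survival via the gamma distribution: T ~ Gamma(f/2, 2c)
    p_pooled = float(stats.gamma.sf(T, a=f / 2.0, scale=2.0 * c))
    p_pooled = min(max(p_pooled, 5e-324), 1.0)
    return GeneResult(gene_id="", k=k, T=T, c=c, f=f, p_pooled=p_pooled)


def fisher_pool(p_values: np.ndarray) -> float:
    """Fisher's method (independence); reference for the LD = I limit."""
    p = np.asarray(p_values, dtype=float)
    T = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(T, df=2 * p.size))


def pool_all_genes(
    results: list[SnpInteractionResult],
    ld_blocks: dict[str, LDMatrix],
    min_snps: int = 2,
    signed: bool = False,
) -> list[GeneResult]:
    """Pool scan results gene by gene.

    Genes with fewer than ``min_snps`` usable (status ok) SNPs are
    excluded and logged; degenerate SNPs reduce a gene's k and its LD
    matrix is subset accordingly.  Output preserves the input gene
    order.  A scanned gene with no LD matrix is a consistency error.
    """
    by_gene: dict[str, list[SnpInteractionResult]] = {}
    order: list[str] = []
    for r in results:
        if not r.gene_id:
            continue
        if r.gene_id not in by_gene:
            by_gene[r.gene_id] = []
            order.append(r.gene_id)
        by_gene[r.gene_id].append(r)
    pooled: list[GeneResult] = []
    for gene_id in order:
        usable = [r for r in by_gene[gene_id] if r.status == STATUS_OK]
        if len(usable) < min_snps:
            logger.info(
                "gene %s: %d usable SNP(s) < %d, excluded from pooling",
                gene_id, len(usable), min_snps,
            )
            continue
        if gene_id not in ld_blocks:
            raise KeyError(f"gene {gene_id!r} has scan results but no LD matrix")
        ld = ld_blocks[gene_id]
        keep_ids = [r.snp_id for r in usable]
        if keep_ids != ld.snp_ids:
            idx = [ld.snp_ids.index(s) for s in keep_ids]
            ld = LDMatrix(snp_ids=keep_ids, r=ld.r[np.ix_(idx, idx)])
        res = brown_pool(np.array([r.p for r in usable]), ld, signed=signed)
        res.gene_id = gene_id
        pooled.append(res)
    return pooled


def bonferroni_threshold(n_genes: int, alpha: float = 0.05) -> float:
    """Per-gene significance threshold alpha / n_genes."""
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    return alpha / n_genes


def mark_significant(
    gene_results: list[GeneResult], alpha: float = 0.05
) -> float:
    """Set each gene's flag against the Bonferroni threshold; returns it."""
    thr = bonferroni_threshold(len(gene_results), alpha) if gene_results else math.nan
    for r in gene_results:
        r.significant = r.p_pooled < thr
    return thr


def results_to_frame(gene_results: list[GeneResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in gene_results],
            "k": [r.k for r in gene_results],
            "T": [r.T for r in gene_results],
            "c": [r.c for r in gene_results],
            "f": [r.f for r in gene_results],
            "p_pooled": [r.p_pooled for r in gene_results],
            "significant": [r.significant for r in gene_results],
        }
    )
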