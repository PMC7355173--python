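"""Per-gene linkage-disequilibrium matrices from dosages.

LD is measured as the signed Pearson correlation r of additive dosages
(the PLINK ``--r`` convention, not r-squared), with pairwise-complete
handling of missing calls.  These matrices feed the dependence
adjustment in the gene-level pooling step.
"""

from __future__ import annotations

import numpy as np

from .data import CohortData, LDMatrix

__all__ = ["genotype_correlation_matrix", "gene_ld_blocks"]


def genotype_correlation_matrix(
    dosages: np.ndarray, snp_ids: list[str]
) -> LDMatrix:
    """Pairwise-complete Pearson correlation of a gene's dosage columns.

    The diagonal is set to exactly 1 and the result symmetrized.  A
    zero-variance SNP (which QC should have removed) is an error naming
    the SNP, as is any pair with fewer than 3 complete observations.
    """
    d = np.asarray(dosages, dtype=float)
    if d.ndim != 2 or d.shape[1] != len(snp_ids):
        raise ValueError("dosage matrix does not match snp_ids")
    k = d.shape[1]
    for j in range(k):
        col = d[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0 or np.var(col) == 0.0:
            raise ValueError(
                f"SNP {snp_ids[j]!r} has zero dosage variance; "
                "run QC before computing LD"
            )
    if not np.isnan(d).any():
        if k == 1:
            return LDMatrix(snp_ids=list(snp_ids), r=np.eye(1))
        if d.shape[0] < 3:
            raise ValueError("fewer than 3 complete observations")
        r = np.clip(np.corrcoef(d, rowvar=False), -1.0, 1.0)
        r = (r + r.T) / 2.0
        np.fill_diagonal(r, 1.0)
        return LDMatrix(snp_ids=list(snp_ids), r=r)
    r = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            mask = ~np.isnan(d[:, i]) & ~np.isnan(d[:, j])
            if mask.sum() < 3:
                raise ValueError(
                    f"fewer than 3 complete observations for pair "
                    f"({snp_ids[i]!r}, {snp_ids[j]!r})"
                )
            x, y = d[mask, i], d[mask, j]
            sx, sy = x.std(), y.std()
            if sx == 0.0 or sy == 0.0:
                raise ValueError(
                    f"zero variance on complete cases for pair "
                    f"({snp_ids[i]!r}, {snp_ids[j]!r})"
                )
            rij = float(np.corrcoef(x, y)[0, 1])
            r[i, j] = r[j, i] = max(-1.0, min(1.0, rij))
    return LDMatrix(snp_ids=list(snp_ids), r=r)


def gene_ld_blocks(cohort: CohortData) -> dict[str, LDMatrix]:
    """One LD matrix per gene, SNP order matching the scan order.

    Genes are keyed in first-appearance order of the gene map; a
    single-SNP gene yields a 1x1 identity.
    """
    blocks: dict[str, LDMatrix] = {}
    for gene_id in cohort.gene_ids():
        snps = cohort.snps_for_gene(gene_id)
        sub = cohort.dosage_submatrix(snps)
        blocks[gene_id] = genotype_correlation_matrix(sub, snps)
    return blocks
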