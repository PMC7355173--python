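"""Core in-memory containers shared across the pipeline.

The analysis operates on a cohort: an additive-dosage genotype matrix
(samples x SNPs, minor-allele counts 0/1/2 with NaN for missing calls),
a SNP-to-gene map, and a per-sample phenotype table holding the outcome
(a continuous symptom score), one or more environmental exposures, and
the covariates age and sex.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortData", "LDMatrix", "GENE_MAP_COLUMNS", "PHENO_ID_COLUMN"]

GENE_MAP_COLUMNS = ["snp_id", "gene_id", "chrom", "pos"]
PHENO_ID_COLUMN = "sample_id"

#: phenotype-table columns that are not exposures
RESERVED_PHENO_COLUMNS = ("symptom_score", "age", "sex")


@dataclass
class CohortData:
    """Aligned genotype matrix, gene map and phenotype/exposure table.

    Parameters
    ----------
    genotypes
        ``(n_samples, n_snps)`` float array of additive dosages in
        ``{0, 1, 2}``; missing calls are ``NaN``.
    snp_ids, sample_ids
        Unique labels for the matrix columns / rows.
    gene_map
        DataFrame with columns ``snp_id, gene_id, chrom, pos`` covering a
        subset of ``snp_ids`` (SNPs without a gene are allowed in the
        matrix but never pooled).
    pheno
        DataFrame indexed by sample id with columns ``symptom_score``,
        ``age``, ``sex`` plus one column per exposure.
    """

    genotypes: np.ndarray
    snp_ids: list[str]
    sample_ids: list[str]
    gene_map: pd.DataFrame
    pheno: pd.DataFrame
    _snp_index: dict[str, int] = field(init=False, repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=float)
        self.snp_ids = [str(s) for s in self.snp_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.validate()
        self._snp_index = {s: i for i, s in enumerate(self.snp_ids)}

    # -- contracts ----------------------------------------------------
    def validate(self) -> None:
        n, m = self.genotypes.shape
        if len(self.sample_ids) != n or len(self.snp_ids) != m:
            raise ValueError(
                f"genotype matrix is {n}x{m} but got {len(self.sample_ids)} "
                f"sample ids and {len(self.snp_ids)} SNP ids"
            )
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.snp_ids)) != m:
            raise ValueError("duplicate SNP ids")
        finite = self.genotypes[~np.isnan(self.genotypes)]
        if finite.size and not np.isin(finite, (0.0, 1.0, 2.0)).all():
            bad = finite[~np.isin(finite, (0.0, 1.0, 2.0))][0]
            raise ValueError(f"dosage value {bad!r} outside {{0,1,2,NA}}")
        missing_cols = [c for c in GENE_MAP_COLUMNS if c not in self.gene_map.columns]
        if missing_cols:
            raise ValueError(f"gene map missing columns {missing_cols}")
        unknown = set(self.gene_map["snp_id"]) - set(self.snp_ids)
        if unknown:
            raise ValueError(f"gene map refers to unknown SNPs: {sorted(unknown)[:5]}")
        if not self.pheno.index.is_unique:
            raise ValueError("duplicate sample ids in phenotype table")
        if set(self.pheno.index.astype(str)) != set(self.sample_ids):
            raise ValueError("phenotype table sample ids do not match genotypes")

    # -- convenience --------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_snps(self) -> int:
        return self.genotypes.shape[1]

    @property
    def exposure_names(self) -> list[str]:
        return [c for c in self.pheno.columns if c not in RESERVED_PHENO_COLUMNS]

    def snp_column(self, snp_id: str) -> np.ndarray:
        return self.genotypes[:, self._snp_index[snp_id]]

    def gene_ids(self) -> list[str]:
        """Gene ids in first-appearance order of the gene map."""
        return list(dict.fromkeys(self.gene_map["gene_id"]))

    def snps_for_gene(self, gene_id: str) -> list[str]:
        sub = self.gene_map.loc[self.gene_map["gene_id"] == gene_id, "snp_id"]
        return list(sub)

    def dosage_submatrix(self, snp_ids: list[str]) -> np.ndarray:
        idx = [self._snp_index[s] for s in snp_ids]
        return self.genotypes[:, idx]

    def aligned_pheno(self) -> pd.DataFrame:
        """Phenotype table reindexed to genotype row order."""
        return self.pheno.reindex(self.sample_ids)

    def with_exposure(self, name: str, values: np.ndarray) -> "CohortData":
        """Return a copy with one exposure column replaced (sensitivity runs)."""
        pheno = self.pheno.copy()
        pheno[name] = np.asarray(values, dtype=float)
        return CohortData(
            genotypes=self.genotypes,
            snp_ids=list(self.snp_ids),
            sample_ids=list(self.sample_ids),
            gene_map=self.gene_map.copy(),
            pheno=pheno,
        )

    def subset_snps(self, keep: list[str]) -> "CohortData":
        keep_set = set(keep)
        idx = [self._snp_index[s] for s in keep]
        gene_map = self.gene_map[self.gene_map["snp_id"].isin(keep_set)].reset_index(
            drop=True
        )
        return CohortData(
            genotypes=self.genotypes[:, idx],
            snp_ids=list(keep),
            sample_ids=list(self.sample_ids),
            gene_map=gene_map,
            pheno=self.pheno.copy(),
        )


@dataclass
class LDMatrix:
    """Per-gene symmetric matrix of pairwise Pearson correlations of dosages.

    Invariants: unit diagonal, entries in [-1, 1], symmetric to 1e-12.
    """

    snp_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.validate()

    def validate(self) -> None:
        k = len(self.snp_ids)
        if self.r.shape != (k, k):
            raise ValueError(f"LD matrix shape {self.r.shape} != ({k},{k})")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-9):
            raise ValueError("LD matrix diagonal must be 1")
        if np.nanmax(np.abs(self.r)) > 1 + 1e-9:
            raise ValueError("LD entries must lie in [-1, 1]")
        if not np.allclose(self.r, self.r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")

    @property
    def k(self) -> int:
        return len(self.snp_ids)

    @classmethod
    def identity(cls, snp_ids: list[str]) -> "LDMatrix":
        return cls(snp_ids=list(snp_ids), r=np.eye(len(snp_ids)))
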