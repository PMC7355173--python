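"""Readers and writers for every on-disk format the pipeline touches.

Formats: PLINK ``.raw`` additive-dosage tables, PLINK ``--r --matrix``
square LD files, TSV phenotype/gene-map tables, and minimal VCF 4.2
(GT-only, biallelic).  All round trips are lossless at machine precision
for in-domain data.  Genome coordinates are 1-based and carried but
never used in computation; missing dosages stay explicit (``NA``), never
imputed at the I/O layer.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import GENE_MAP_COLUMNS, LDMatrix

__all__ = [
    "ParseError",
    "read_genotype_table",
    "write_genotype_table",
    "read_ld_square",
    "write_ld_square",
    "read_pheno_table",
    "write_pheno_table",
    "read_gene_map",
    "write_gene_map",
    "read_vcf_genotypes",
    "write_vcf_genotypes",
]

logger = logging.getLogger(__name__)

RAW_META_COLUMNS = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]


class ParseError(ValueError):
    """Malformed input file; the message names the offending row/column."""


# ---------------------------------------------------------------------------
# PLINK .raw dosage tables


def read_genotype_table(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read a PLINK ``.raw``-style additive dosage table.

    Returns ``(genotypes, sample_ids, snp_ids)``; sample ids come from
    the IID column and the ``_<allele>`` suffix is stripped from SNP
    headers.  ``NA`` becomes NaN; any cell outside {0,1,2,NA} is a
    :class:`ParseError` naming row and column.
    """
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().split()
    if header[: len(RAW_META_COLUMNS)] != RAW_META_COLUMNS:
        raise ParseError(
            f"{path}: header must start with {' '.join(RAW_META_COLUMNS)}"
        )
    snp_cols = header[len(RAW_META_COLUMNS) :]
    snp_ids = [c.rsplit("_", 1)[0] if "_" in c else c for c in snp_cols]
    df = pd.read_csv(
        path, sep=r"\s+", dtype=str, na_values=["NA"], keep_default_na=False
    )
    sample_ids = df["IID"].astype(str).tolist()
    geno = np.full((len(df), len(snp_cols)), np.nan)
    for j, col in enumerate(snp_cols):
        raw = df[col]
        present = raw.notna()
        vals = pd.to_numeric(raw[present], errors="coerce")
        bad = vals.isna() | ~vals.isin([0, 1, 2])
        if bad.any():
            row = bad.idxmax()
            raise ParseError(
                f"{path}: invalid dosage {raw[row]!r} at sample "
                f"{df['IID'][row]!r}, SNP column {col!r}"
            )
        geno[present.to_numpy(), j] = vals.to_numpy(dtype=float)
    return geno, sample_ids, snp_ids


def write_genotype_table(
    path: str | Path,
    genotypes: np.ndarray,
    sample_ids: list[str],
    snp_ids: list[str],
    sex: np.ndarray | None = None,
    allele: str = "A",
) -> None:
    """Write dosages in the PLINK ``.raw`` dialect (``NA`` for missing).

    SEX uses PLINK coding (1 = male, 2 = female) when ``sex`` (0/1,
    1 = male) is given, else 0; PHENOTYPE is -9 (not carried here).
    """
    path = Path(path)
    geno = np.asarray(genotypes, dtype=float)
    header = RAW_META_COLUMNS + [f"{s}_{allele}" for s in snp_ids]
    sex_codes = (
        np.where(np.asarray(sex) == 1, 1, 2).astype(int)
        if sex is not None
        else np.zeros(len(sample_ids), dtype=int)
    )
    with path.open("w") as fh:
        fh.write(" ".join(header) + "\n")
        for i, sid in enumerate(sample_ids):
            cells = [
                "NA" if np.isnan(v) else str(int(v)) for v in geno[i]
            ]
            fh.write(
                f"{sid} {sid} 0 0 {sex_codes[i]} -9 " + " ".join(cells) + "\n"
            )


# ---------------------------------------------------------------------------
# PLINK .ld square matrices


def read_ld_square(path: str | Path, snp_ids: list[str]) -> LDMatrix:
    """Read a PLINK ``--r --matrix`` square file for the given SNPs.

    The matrix is symmetrized by averaging when the asymmetry is within
    1e-6 (round-off in printed files); larger asymmetry is an error, as
    is any entry outside [-1, 1] beyond 1e-9.
    """
    path = Path(path)
    r = np.loadtxt(path, ndmin=2)
    k = len(snp_ids)
    if r.shape != (k, k):
        raise ParseError(
            f"{path}: expected a {k}x{k} matrix for {k} SNPs, got {r.shape}"
        )
    if np.nanmax(np.abs(r)) > 1 + 1e-9:
        raise ParseError(f"{path}: correlation entries must lie in [-1, 1]")
    asym = np.nanmax(np.abs(r - r.T)) if k > 1 else 0.0
    if asym > 1e-6:
        raise ParseError(f"{path}: matrix asymmetric by {asym:.2e} (> 1e-6)")
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return LDMatrix(snp_ids=list(snp_ids), r=r)


def write_ld_square(path: str | Path, ld: LDMatrix) -> None:
    np.savetxt(path, ld.r, fmt="%.10g")


# ---------------------------------------------------------------------------
# TSV tables


def read_pheno_table(path: str | Path) -> pd.DataFrame:
    """Read the phenotype/exposure/covariate TSV (index: sample_id).

    Requires ``sample_id``, ``symptom_score``, ``age`` and ``sex``
    columns; everything else is treated as an exposure.  Sex must be
    coded 0/1; duplicate sample ids are rejected.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "symptom_score", "age", "sex"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate sample id {dup!r}")
    sex = pd.to_numeric(df["sex"], errors="coerce")
    if sex.isna().any() or not sex.isin([0, 1]).all():
        raise ParseError(f"{path}: column 'sex' must be coded 0/1")
    df["sex"] = sex.astype(float)
    return df.set_index("sample_id")


def write_pheno_table(path: str | Path, pheno: pd.DataFrame) -> None:
    out = pheno.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_gene_map(path: str | Path) -> pd.DataFrame:
    """Read the SNP-to-gene TSV (snp_id, gene_id, chrom, pos; 1-based)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "gene_id": str})
    missing = [c for c in GENE_MAP_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing required column(s) {missing}")
    if df["snp_id"].duplicated().any():
        dup = df["snp_id"][df["snp_id"].duplicated()].iloc[0]
        raise ParseError(f"{path}: duplicate snp_id {dup!r}")
    df["pos"] = df["pos"].astype(int)
    return df[GENE_MAP_COLUMNS].reset_index(drop=True)


def write_gene_map(path: str | Path, gene_map: pd.DataFrame) -> None:
    gene_map[GENE_MAP_COLUMNS].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# minimal VCF 4.2 (GT only, biallelic)

def read_vcf_genotypes(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read GT dosages from a (plain-text) VCF 4.2.

    Multiallelic records are skipped with a logged warning.  Returns
    ``(genotypes, sample_ids, snp_ids)`` with the ALT-allele count as
    dosage and ``./.`` as NaN.
    """
    from cyvcf2 import VCF  # heavy import, only needed for VCF input

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    snp_ids: list[str] = []
    rows: list[np.ndarray] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            logger.warning(
                "skipping multiallelic record %s at %s:%d",
                rec.ID or ".",
                rec.CHROM,
                rec.POS,
            )
            continue
        gts = np.array(rec.genotypes)  # rows of [allele1, allele2, phased]
        dos = gts[:, 0].astype(float) + gts[:, 1].astype(float)
        dos[(gts[:, 0] < 0) | (gts[:, 1] < 0)] = np.nan
        rows.append(dos)
        snp_ids.append(rec.ID or f"{rec.CHROM}:{rec.POS}")
    geno = np.array(rows).T if rows else np.empty((len(sample_ids), 0))
    return geno, sample_ids, snp_ids


def write_vcf_genotypes(
    path: str | Path,
    genotypes: np.ndarray,
    sample_ids: list[str],
    snp_ids: list[str],
    gene_map: pd.DataFrame | None = None,
) -> None:
    """Write dosages as a minimal GT-only VCF 4.2 (REF=A, ALT=G).

    Dosage 0/1/2 maps to 0/0, 0/1, 1/1; missing to ``./.``.  Positions
    come from ``gene_map`` when given, else chrom 1 with consecutive
    1-based positions.
    """
    geno = np.asarray(genotypes, dtype=float)
    gt_str = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    snp_pos = (
        {row.snp_id: (row.chrom, row.pos) for row in gene_map.itertuples()}
        if gene_map is not None
        else {}
    )
    with Path(path).open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_ids)
            + "\n"
        )
        for j, snp_id in enumerate(snp_ids):
            chrom, pos = snp_pos.get(snp_id, (1, j + 1))
            calls = [
                "./." if np.isnan(v) else gt_str[v] for v in geno[:, j]
            ]
            fh.write(
                f"{chrom}\t{pos}\t{snp_id}\tA\tG\t.\tPASS\t.\tGT\t"
                + "\t".join(calls)
                + "\n"
            )
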