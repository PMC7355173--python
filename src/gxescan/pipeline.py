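"""End-to-end orchestration: simulate/load -> QC -> scan -> pool -> validate.

A run is driven by one :class:`RunConfig` (built in code or loaded from
YAML) and writes a self-contained run directory: QC report, per-exposure
scan and gene tables, Manhattan-style tables, genomic-control lambdas,
optional permutation tables, a machine-readable ``summary.json``, and a
log with per-stage timings and every seed used, so any run is
replayable.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as gio
from .combine import mark_significant, pool_all_genes, results_to_frame as gene_frame
from .data import CohortData
from .ld import gene_ld_blocks
from .qc import QcThresholds, apply_qc
from .scan import ScanModelSpec, results_to_frame as scan_frame, scan_all
from .simulate import SimConfig, simulate_cohort
from .validate import (
    dichotomize_exposure,
    genomic_control_lambda,
    permutation_test,
)

__all__ = ["RunConfig", "run_pipeline", "manhattan_table", "load_cohort"]

logger = logging.getLogger(__name__)

LOG10_FLOOR = 1e-300


@dataclass
class RunConfig:
    """Full parameterization of one pipeline run.

    Exactly one of ``sim`` (generate a cohort) or the three input paths
    (load a cohort) must be provided.  ``exposures`` defaults to every
    non-covariate column of the phenotype table.
    """

    out_dir: str | Path = "gxescan_run"
    seed: int = 0
    sim: SimConfig | None = None
    genotype_path: str | None = None
    gene_map_path: str | None = None
    pheno_path: str | None = None
    exposures: list[str] | None = None
    covariates: tuple[str, ...] = ("age", "sex")
    keller_terms: bool = True
    min_nonmissing: int = 30
    qc: QcThresholds = field(default_factory=QcThresholds)
    min_snps_per_gene: int = 2
    signed_ld: bool = False
    alpha: float = 0.05
    n_perm: int = 0  # 0 disables the permutation stage
    perm_strategy: str = "phenotype"
    binary_exposure: str | None = None  # dichotomization method or None
    plot: bool = False
    log_level: str = "INFO"

    def validate(self) -> None:
        paths = [self.genotype_path, self.gene_map_path, self.pheno_path]
        has_paths = all(p is not None for p in paths)
        some_paths = any(p is not None for p in paths)
        if self.sim is not None and some_paths:
            raise ValueError("provide either sim or input paths, not both")
        if self.sim is None and not has_paths:
            raise ValueError(
                "provide sim or all of genotype_path/gene_map_path/pheno_path"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        raw = dict(raw)
        if "sim" in raw and raw["sim"] is not None:
            from .simulate import EffectSpec, ExposureSpec, GeneSpec

            sim_raw = dict(raw["sim"])
            if "genes" in sim_raw:
                sim_raw["genes"] = [GeneSpec(**g) for g in sim_raw["genes"]]
            if "exposures" in sim_raw:
                sim_raw["exposures"] = [
                    ExposureSpec(**e) for e in sim_raw["exposures"]
                ]
            if "effect" in sim_raw:
                sim_raw["effect"] = EffectSpec(**sim_raw["effect"])
            raw["sim"] = SimConfig(**sim_raw)
        if "qc" in raw and raw["qc"] is not None:
            raw["qc"] = QcThresholds(**raw["qc"])
        if "covariates" in raw:
            raw["covariates"] = tuple(raw["covariates"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d


def load_cohort(config: RunConfig) -> CohortData:
    """Materialize the cohort: simulate when ``sim`` is set, else read
    the genotype/gene-map/phenotype files."""
    if config.sim is not None:
        return simulate_cohort(config.sim)
    geno, sample_ids, snp_ids = gio.read_genotype_table(config.genotype_path)
    gene_map = gio.read_gene_map(config.gene_map_path)
    pheno = gio.read_pheno_table(config.pheno_path)
    return CohortData(
        genotypes=geno,
        snp_ids=snp_ids,
        sample_ids=sample_ids,
        gene_map=gene_map,
        pheno=pheno,
    )


def manhattan_table(gene_results: list) -> pd.DataFrame:
    """Gene table for Manhattan-style plotting, input gene order.

    Columns: gene_id, k, p_pooled, neg_log10_p (underflow floored at
    1e-300), significant.
    """
    if not gene_results:
        raise ValueError("no gene results")
    df = gene_frame(gene_results)
    df["neg_log10_p"] = -np.log10(np.maximum(df["p_pooled"], LOG10_FLOOR))
    return df[["gene_id", "k", "p_pooled", "neg_log10_p", "significant"]]


def plot_manhattan(table: pd.DataFrame, threshold: float, path: str | Path,
                   title: str = "") -> None:
    """Bar-style gene Manhattan plot with the Bonferroni line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, len(table) * 0.04), 4))
    ax.bar(range(len(table)), table["neg_log10_p"], width=0.8, color="#30648e")
    ax.axhline(-np.log10(threshold), ls="--", color="red", lw=1)
    ax.set_xlabel("gene")
    ax.set_ylabel(r"$-\log_{10} p$")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _stage(log: list, name: str, t0: float) -> float:
    t1 = time.perf_counter()
    entry = {"stage": name, "seconds": round(t1 - t0, 3)}
    log.append(entry)
    logger.info("stage %-12s %.3fs", name, t1 - t0)
    return t1


def run_pipeline(config: RunConfig) -> dict:
    """Run the whole analysis and write every artifact to ``out_dir``.

    Returns the summary dictionary (also written to ``summary.json``):
    SNP counts in/out of QC, genes tested per exposure, the Bonferroni
    threshold, lambda, and the significant genes.  Stage failures
    propagate with the failing stage named; artifacts written before the
    failure are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    timings: list[dict] = []
    t0 = time.perf_counter()
    stage = "load"
    try:
        cohort = load_cohort(config)
        t0 = _stage(timings, "load", t0)

        stage = "qc"
        cohort_qc, qc_report = apply_qc(cohort, config.qc)
        qc_report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        t0 = _stage(timings, "qc", t0)

        stage = "ld"
        ld_blocks = gene_ld_blocks(cohort_qc)
        t0 = _stage(timings, "ld", t0)

        exposures = config.exposures or cohort_qc.exposure_names
        spec_kwargs = dict(
            covariates=config.covariates,
            keller_terms=config.keller_terms,
            min_nonmissing=config.min_nonmissing,
        )
        summary: dict = {
            "seed": config.seed,
            "n_samples": cohort.n_samples,
            "n_snps_input": cohort.n_snps,
            "n_snps_after_qc": cohort_qc.n_snps,
            "exposures": {},
        }
        for exposure in exposures:
            stage = f"scan[{exposure}]"
            spec = ScanModelSpec(exposure=exposure, **spec_kwargs)
            run_cohort = cohort_qc
            if config.binary_exposure:
                e = cohort_qc.aligned_pheno()[exposure].to_numpy(dtype=float)
                run_cohort = cohort_qc.with_exposure(
                    exposure, dichotomize_exposure(e, config.binary_exposure)
                )
            snp_results = scan_all(run_cohort, spec)
            scan_frame(snp_results).to_csv(
                out / f"scan_{exposure}.tsv", sep="\t", index=False
            )
            t0 = _stage(timings, f"scan[{exposure}]", t0)

            stage = f"pool[{exposure}]"
            gene_results = pool_all_genes(
                snp_results, ld_blocks,
                min_snps=config.min_snps_per_gene, signed=config.signed_ld,
            )
            threshold = mark_significant(gene_results, config.alpha)
            gene_frame(gene_results).to_csv(
                out / f"genes_{exposure}.tsv", sep="\t", index=False
            )
            table = manhattan_table(gene_results)
            table.to_csv(out / f"manhattan_{exposure}.tsv", sep="\t", index=False)
            if config.plot:
                plot_manhattan(
                    table, threshold, out / f"manhattan_{exposure}.png",
                    title=exposure,
                )
            lam = genomic_control_lambda(
                np.array([g.p_pooled for g in gene_results])
            )
            t0 = _stage(timings, f"pool[{exposure}]", t0)

            exp_summary = {
                "n_genes_tested": len(gene_results),
                "bonferroni_threshold": threshold,
                "lambda_gc": lam,
                "significant_genes": [
                    g.gene_id for g in gene_results if g.significant
                ],
            }
            if config.n_perm > 0:
                stage = f"permute[{exposure}]"
                _, perms = permutation_test(
                    run_cohort, spec, ld_blocks,
                    n_perm=config.n_perm, strategy=config.perm_strategy,
                    seed=config.seed, min_snps=config.min_snps_per_gene,
                    signed=config.signed_ld,
                )
                pd.DataFrame([dataclasses.asdict(p) for p in perms]).to_csv(
                    out / f"permutation_{exposure}.tsv", sep="\t", index=False
                )
                exp_summary["n_perm"] = config.n_perm
                exp_summary["perm_strategy"] = config.perm_strategy
                t0 = _stage(timings, f"permute[{exposure}]", t0)
            summary["exposures"][exposure] = exp_summary
    except Exception as exc:
        logger.error("pipeline failed in stage %s: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    summary["timings"] = timings
    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
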