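"""Seeded synthetic cohorts with the structure the analysis assumes.

The generator emulates an adolescent G-by-E cohort: ~948 individuals,
genes of 2+ SNPs with decaying within-gene linkage disequilibrium,
five bounded parenting-style exposures on a 1-5 scale (one of them
strongly right-skewed with a point mass at the scale floor, like harsh
punitive control), age ~ Normal(13.78, 0.92^2), sex ~ Bernoulli(0.505),
and a continuous symptom score with optional embedded G-by-E effects.

Genotypes are built from two independent haplotypes per individual.
Each haplotype is a thresholded draw from a latent Gaussian with AR(1)
correlation ``ld_rho`` along the gene's SNPs; the threshold is the
normal quantile of the SNP's minor-allele frequency, so the marginal
allele frequency is exactly the drawn MAF and dosages are in
Hardy-Weinberg equilibrium by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortData, GENE_MAP_COLUMNS

__all__ = [
    "GeneSpec",
    "ExposureSpec",
    "EffectSpec",
    "SimConfig",
    "default_exposures",
    "default_genes",
    "simulate_genotypes",
    "simulate_exposures_covariates",
    "simulate_phenotype",
    "simulate_cohort",
    "gxe_beta_for_power",
]

SCALE_MIN, SCALE_MAX = 1.0, 5.0


class ConfigurationError(ValueError):
    """Raised for invalid simulation parameters."""


class AlignmentError(ValueError):
    """Raised when sample-aligned inputs disagree in length."""


@dataclass
class GeneSpec:
    """One simulated gene: SNP count, latent AR(1) LD, and MAF range."""

    gene_id: str
    n_snps: int
    ld_rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)

    def validate(self) -> None:
        if self.n_snps < 1:
            raise ConfigurationError(f"{self.gene_id}: n_snps must be >= 1")
        if not 0.0 <= self.ld_rho <= 1.0:
            raise ConfigurationError(f"{self.gene_id}: ld_rho must be in [0,1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"{self.gene_id}: maf_range must lie within (0, 0.5]"
            )


@dataclass
class ExposureSpec:
    """A bounded exposure on the 1-5 questionnaire scale.

    ``bounded_normal``: Gaussian draws clipped to [1, 5].
    ``right_skewed``: point mass at the scale floor (``floor_mass`` of
    samples exactly 1.0) plus ``1 + Gamma(shape, scale)`` clipped to
    [1, 5] for the rest -- emulates a rare-adversity dimension whose
    median coincides with the minimum.
    """

    name: str
    distribution: str = "bounded_normal"  # or "right_skewed"
    mean: float = 3.0
    sd: float = 0.8
    floor_mass: float = 0.55
    gamma_shape: float = 1.2
    gamma_scale: float = 0.9

    def validate(self) -> None:
        if self.distribution not in ("bounded_normal", "right_skewed"):
            raise ConfigurationError(f"unknown distribution {self.distribution!r}")
        if self.sd < 0:
            raise ConfigurationError(f"{self.name}: sd must be >= 0")
        if not 0.0 <= self.floor_mass <= 1.0:
            raise ConfigurationError(f"{self.name}: floor_mass must be in [0,1]")


@dataclass
class EffectSpec:
    """Linear data-generating model for the symptom score.

    y = b0 + beta_g*g + beta_e*e + beta_gxe*(g*e) + beta_age*age
        + beta_sex*sex + eps,   eps ~ N(0, noise_sd^2)

    When ``target_gene`` is set, the genetic terms sum over every SNP of
    that gene; otherwise all genetic effects are zero.
    """

    target_gene: str | None = None
    exposure: str | None = None  # default: first configured exposure
    intercept: float = 0.0
    beta_g: float = 0.0
    beta_e: float = 0.0
    beta_gxe: float = 0.0
    beta_age: float = 0.0
    beta_sex: float = 0.0
    noise_sd: float = 1.0

    def validate(self) -> None:
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be > 0")


def default_exposures() -> list[ExposureSpec]:
    """Five parenting-style dimensions; harsh punitive control is the
    right-skewed one (scale means/SDs are generator placeholders)."""
    return [
        ExposureSpec("support", "bounded_normal", mean=3.8, sd=0.7),
        ExposureSpec("proactive_control", "bounded_normal", mean=3.2, sd=0.7),
        ExposureSpec("psychological_control", "bounded_normal", mean=2.0, sd=0.7),
        ExposureSpec("punitive_control", "bounded_normal", mean=2.2, sd=0.8),
        ExposureSpec("harsh_punitive_control", "right_skewed"),
    ]


def default_genes(
    n_genes: int = 50,
    min_snps: int = 2,
    max_snps: int = 6,
    ld_rhos: tuple[float, ...] = (0.2, 0.5, 0.8),
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> list[GeneSpec]:
    """A deterministic desk-scale gene panel: sizes and LD strengths cycle."""
    sizes = list(range(min_snps, max_snps + 1))
    return [
        GeneSpec(
            gene_id=f"G{i + 1:04d}",
            n_snps=sizes[i % len(sizes)],
            ld_rho=ld_rhos[i % len(ld_rhos)],
            maf_range=maf_range,
        )
        for i in range(n_genes)
    ]


@dataclass
class SimConfig:
    """Full parameterization (and seed) of the synthetic cohort generator."""

    n_individuals: int = 948
    genes: list[GeneSpec] = field(default_factory=default_genes)
    exposures: list[ExposureSpec] = field(default_factory=default_exposures)
    age_mean: float = 13.78
    age_sd: float = 0.92
    prob_male: float = 0.505
    effect: EffectSpec = field(default_factory=EffectSpec)
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 1:
            raise ConfigurationError("n_individuals must be >= 1")
        if not self.genes:
            raise ConfigurationError("at least one gene is required")
        if not 0.0 <= self.prob_male <= 1.0:
            raise ConfigurationError("prob_male must be in [0,1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ConfigurationError("missing_rate must be in [0,1)")
        if self.age_sd < 0:
            raise ConfigurationError("age_sd must be >= 0")
        seen: set[str] = set()
        for g in self.genes:
            g.validate()
            if g.gene_id in seen:
                raise ConfigurationError(f"duplicate gene id {g.gene_id}")
            seen.add(g.gene_id)
        for e in self.exposures:
            e.validate()
        self.effect.validate()
        if self.effect.target_gene is not None and self.effect.target_gene not in seen:
            raise ConfigurationError(
                f"effect target_gene {self.effect.target_gene!r} not in gene list"
            )


# ---------------------------------------------------------------------------
# genotypes


def _ar1_latent(rng: np.random.Generator, n: int, k: int, rho: float) -> np.ndarray:
    """n x k standard-normal draws with AR(1) correlation rho across columns."""
    z = rng.standard_normal((n, k))
    if rho > 0:
        scale = math.sqrt(1.0 - rho * rho)
        for j in range(1, k):
            z[:, j] = rho * z[:, j - 1] + scale * z[:, j]
    return z


def simulate_genotypes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, list[str], pd.DataFrame]:
    """Simulate the dosage matrix and gene map.

    Returns ``(genotypes, snp_ids, gene_map)`` where genotypes is the
    ``n_individuals x n_snps`` matrix of minor-allele counts.  Two
    independent haplotypes per individual guarantee HWE marginally;
    within a gene, SNPs share a latent AR(1) Gaussian so adjacent SNPs
    are in LD with decaying correlation.  Deterministic given the seed.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    blocks: list[np.ndarray] = []
    snp_ids: list[str] = []
    map_rows: list[tuple[str, str, int, int]] = []
    pos = 1
    for gi, gene in enumerate(config.genes):
        k = gene.n_snps
        mafs = rng.uniform(gene.maf_range[0], gene.maf_range[1], size=k)
        thresholds = stats.norm.ppf(mafs)
        hap1 = (_ar1_latent(rng, n, k, gene.ld_rho) < thresholds).astype(float)
        hap2 = (_ar1_latent(rng, n, k, gene.ld_rho) < thresholds).astype(float)
        blocks.append(hap1 + hap2)
        chrom = gi % 22 + 1
        for j in range(k):
            sid = f"{gene.gene_id}_snp{j + 1}"
            snp_ids.append(sid)
            map_rows.append((sid, gene.gene_id, chrom, pos))
            pos += 1000
    genotypes = np.concatenate(blocks, axis=1)
    if config.missing_rate > 0:
        mask = rng.random(genotypes.shape) < config.missing_rate
        genotypes[mask] = np.nan
    gene_map = pd.DataFrame(map_rows, columns=GENE_MAP_COLUMNS)
    return genotypes, snp_ids, gene_map


# ---------------------------------------------------------------------------
# exposures + covariates


def _draw_exposure(
    spec: ExposureSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    if spec.distribution == "bounded_normal":
        vals = rng.normal(spec.mean, spec.sd, size=n)
        return np.clip(vals, SCALE_MIN, SCALE_MAX)
    # right_skewed: floor point mass + gamma tail, clipped to the scale
    at_floor = rng.random(n) < spec.floor_mass
    tail = SCALE_MIN + rng.gamma(spec.gamma_shape, spec.gamma_scale, size=n)
    vals = np.where(at_floor, SCALE_MIN, np.clip(tail, SCALE_MIN, SCALE_MAX))
    return vals


def simulate_exposures_covariates(
    config: SimConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Per-sample exposure, age and sex table (index: sample id).

    Exposures always lie in [1, 5].  Age is Normal(age_mean, age_sd^2);
    sex is Bernoulli(prob_male) coded 1 = male.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    table: dict[str, np.ndarray] = {}
    for spec in config.exposures:
        table[spec.name] = _draw_exposure(spec, n, rng)
    table["age"] = rng.normal(config.age_mean, config.age_sd, size=n)
    table["sex"] = (rng.random(n) < config.prob_male).astype(float)
    idx = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="sample_id")
    return pd.DataFrame(table, index=idx)


# ---------------------------------------------------------------------------
# phenotype


def simulate_phenotype(
    genotypes: np.ndarray,
    snp_ids: list[str],
    gene_map: pd.DataFrame,
    covariates: pd.DataFrame,
    effect: EffectSpec,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Symptom-score vector under the linear G-by-E generating model.

    Genetic and interaction contributions sum over every SNP of the
    target gene (missing dosages contribute zero).  Inputs must be
    sample-aligned; ``covariates`` needs columns ``age``, ``sex`` and the
    effect's exposure.
    """
    effect.validate()
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    n = len(covariates)
    if genotypes.shape[0] != n:
        raise AlignmentError(
            f"genotypes have {genotypes.shape[0]} rows but covariates {n}"
        )
    exposure = effect.exposure
    if exposure is None:
        non_cov = [c for c in covariates.columns if c not in ("age", "sex")]
        if not non_cov:
            raise AlignmentError("no exposure column available")
        exposure = non_cov[0]
    e = covariates[exposure].to_numpy(dtype=float)
    y = (
        effect.intercept
        + effect.beta_e * e
        + effect.beta_age * covariates["age"].to_numpy(dtype=float)
        + effect.beta_sex * covariates["sex"].to_numpy(dtype=float)
        + rng.normal(0.0, effect.noise_sd, size=n)
    )
    if effect.target_gene is not None and (effect.beta_g or effect.beta_gxe):
        targets = gene_map.loc[gene_map["gene_id"] == effect.target_gene, "snp_id"]
        col = {s: i for i, s in enumerate(snp_ids)}
        g_block = genotypes[:, [col[s] for s in targets]]
        g_sum = np.nansum(g_block, axis=1)
        y = y + effect.beta_g * g_sum + effect.beta_gxe * g_sum * e
    return y


def simulate_cohort(config: SimConfig) -> CohortData:
    """Generate a complete, aligned synthetic cohort from one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    genotypes, snp_ids, gene_map = simulate_genotypes(config, rng)
    pheno = simulate_exposures_covariates(config, rng)
    y = simulate_phenotype(genotypes, snp_ids, gene_map, pheno, config.effect, rng)
    pheno.insert(0, "symptom_score", y)
    return CohortData(
        genotypes=genotypes,
        snp_ids=snp_ids,
        sample_ids=list(pheno.index),
        gene_map=gene_map,
        pheno=pheno,
    )


# ---------------------------------------------------------------------------
# effect-size calibration


def gxe_beta_for_power(
    config: SimConfig,
    exposure: str,
    power: float = 0.8,
    alpha: float = 0.05,
    maf: float = 0.3,
    n_mc: int = 20000,
    seed: int = 12345,
) -> float:
    """Interaction coefficient giving a single-SNP scan ~``power``.

    Uses a Monte-Carlo estimate (seeded, independent of the cohort seed)
    of the residual variance of the g*e regressor after projection on
    the other design columns, then inverts the two-sided t-test power
    relation: beta = (z_{1-alpha/2} + z_{power}) * noise_sd /
    sqrt(n * var_resid(g*e)).
    """
    rng = np.random.default_rng(seed)
    probe = SimConfig(
        n_individuals=n_mc,
        genes=[GeneSpec("PROBE", 1, 0.0, (maf, maf))],
        exposures=config.exposures,
        age_mean=config.age_mean,
        age_sd=config.age_sd,
        prob_male=config.prob_male,
        seed=seed,
    )
    g, _, _ = simulate_genotypes(probe, rng)
    cov = simulate_exposures_covariates(probe, rng)
    e = cov[exposure].to_numpy()
    ge = g[:, 0] * e
    X = np.column_stack(
        [np.ones(n_mc), g[:, 0], e, cov["age"].to_numpy(), cov["sex"].to_numpy()]
    )
    resid = ge - X @ np.linalg.lstsq(X, ge, rcond=None)[0]
    var_resid = float(resid @ resid) / n_mc
    z = stats.norm.ppf(1 - alpha / 2) + stats.norm.ppf(power)
    return float(
        z * config.effect.noise_sd / math.sqrt(config.n_individuals * var_resid)
    )
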