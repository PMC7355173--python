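"""SNP-level quality control.

Filters follow standard GWAS practice with strict-inequality thresholds:
SNPs with a call rate below 98% or a minor allele frequency below 1%
are excluded, and an optional Hardy-Weinberg equilibrium filter removes
SNPs whose genotype counts deviate from HWE at ``hwe_alpha``.  Filters
run in the order call-rate, MAF, HWE and report the first failure per
SNP.  Call rate counts individuals; MAF counts alleles among
non-missing genotypes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortData

__all__ = ["QcThresholds", "compute_maf", "compute_call_rate", "hwe_test", "apply_qc"]

logger = logging.getLogger(__name__)

QC_REPORT_COLUMNS = ["snp_id", "call_rate", "maf", "hwe_p", "kept", "reason"]


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion rules: strict inequalities against each threshold.

    ``hwe_alpha = 0`` disables the HWE filter (p-values are still
    reported); the 1e-6 default is the conventional GWAS cut-off.
    """

    call_rate_min: float = 0.98
    maf_min: float = 0.01
    hwe_alpha: float = 1e-6
    hwe_method: str = "chi2"  # or "exact"


def compute_call_rate(dosages: np.ndarray) -> float:
    """Fraction of individuals with a non-missing genotype call."""
    d = np.asarray(dosages, dtype=float)
    if d.size == 0:
        raise ValueError("empty dosage vector")
    return float(np.sum(~np.isnan(d))) / d.size


def compute_maf(dosages: np.ndarray) -> float:
    """Minor allele frequency among non-missing genotypes.

    The alternate-allele frequency is folded to ``min(f, 1 - f)``; an
    all-missing vector has no defined MAF and raises.
    """
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        raise ValueError("MAF undefined: all genotypes missing")
    f = float(d.sum()) / (2 * d.size)
    return min(f, 1.0 - f)


def _hwe_chi2(n_AA: int, n_Aa: int, n_aa: int) -> float:
    n = n_AA + n_Aa + n_aa
    p = (2 * n_AA + n_Aa) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:  # monomorphic: trivially in HWE
        return 1.0
    exp = np.array([p * p * n, 2 * p * q * n, q * q * n])
    obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
    chi2 = float(((obs - exp) ** 2 / exp).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _hwe_exact(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE test by enumeration over heterozygote counts.

    Sums the conditional probabilities (given allele counts) of every
    genotype configuration no more probable than the observed one — the
    standard exact test without the mid-p correction.
    """
    n = n_AA + n_Aa + n_aa
    n_a = n_Aa + 2 * n_aa  # rarer-allele count after folding below
    n_A = n_Aa + 2 * n_AA
    if n_a > n_A:
        n_a, n_A = n_A, n_a
    if n_a == 0:
        return 1.0
    # heterozygote counts share the parity of the minor-allele count
    het_min = n_a % 2
    hets = np.arange(het_min, n_a + 1, 2)
    # unnormalized log-probabilities of the conditional distribution
    from scipy.special import gammaln

    def log_w(h: np.ndarray) -> np.ndarray:
        hom_a = (n_a - h) // 2
        hom_A = n - h - hom_a
        return (
            h * np.log(2.0)
            - gammaln(h + 1)
            - gammaln(hom_a + 1)
            - gammaln(hom_A + 1)
        )

    lw = log_w(hets)
    lw -= lw.max()
    w = np.exp(lw)
    w /= w.sum()
    obs_het = n_Aa
    p_obs = w[np.searchsorted(hets, obs_het)]
    return float(min(1.0, w[w <= p_obs * (1 + 1e-12)].sum()))


def hwe_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "chi2") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``chi2``: 1-df goodness-of-fit test of observed vs HWE-expected
    counts at the sample allele frequency.  ``exact``: exact conditional
    test enumerating heterozygote counts.  Returns a p-value in (0, 1].
    """
    for c in (n_AA, n_Aa, n_aa):
        if c < 0:
            raise ValueError("genotype counts must be non-negative")
    if n_AA + n_Aa + n_aa == 0:
        raise ValueError("total genotype count must be positive")
    if method == "chi2":
        return max(_hwe_chi2(n_AA, n_Aa, n_aa), np.nextafter(0.0, 1.0))
    if method == "exact":
        return max(_hwe_exact(n_AA, n_Aa, n_aa), np.nextafter(0.0, 1.0))
    raise ValueError(f"unknown HWE method {method!r}")


def _hwe_p_for_column(d: np.ndarray, method: str) -> float:
    d = d[~np.isnan(d)]
    if d.size == 0:
        return np.nan
    n_hom_ref = int((d == 0).sum())
    n_het = int((d == 1).sum())
    n_hom_alt = int((d == 2).sum())
    return hwe_test(n_hom_ref, n_het, n_hom_alt, method=method)


def apply_qc(
    cohort: CohortData, thresholds: QcThresholds | None = None
) -> tuple[CohortData, pd.DataFrame]:
    """Filter SNPs by call rate, MAF and (optionally) HWE.

    Returns the filtered cohort (gene map pruned consistently) and a
    per-SNP report with every metric, the kept flag, and the first
    failing filter as the reason.  Removing every SNP is a warning, not
    an error.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if cohort.n_snps < 1:
        raise ValueError("cohort has no SNPs")
    rows = []
    keep: list[str] = []
    for j, snp_id in enumerate(cohort.snp_ids):
        d = cohort.genotypes[:, j]
        call_rate = compute_call_rate(d)
        all_missing = np.isnan(d).all()
        maf = np.nan if all_missing else compute_maf(d)
        hwe_p = _hwe_p_for_column(d, thresholds.hwe_method)
        reason = ""
        if call_rate < thresholds.call_rate_min:
            reason = "call_rate"
        elif all_missing or maf < thresholds.maf_min:
            reason = "maf" if not all_missing else "call_rate"
        elif thresholds.hwe_alpha > 0 and hwe_p < thresholds.hwe_alpha:
            reason = "hwe"
        kept = reason == ""
        if kept:
            keep.append(snp_id)
        rows.append((snp_id, call_rate, maf, hwe_p, kept, reason))
    report = pd.DataFrame(rows, columns=QC_REPORT_COLUMNS)
    if not keep:
        warnings.warn("QC removed every SNP; returning an empty cohort")
        logger.warning("QC removed all %d SNPs", cohort.n_snps)
    filtered = cohort.subset_snps(keep)
    logger.info("QC kept %d of %d SNPs", len(keep), cohort.n_snps)
    return filtered, report
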