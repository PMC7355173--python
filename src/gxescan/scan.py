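"""Per-SNP linear G-by-E interaction scan.

For each SNP the model

    symptom_score ~ 1 + g + e + g*e + age + sex [+ age*g + age*e + sex*g + sex*e]

is fit by ordinary least squares on complete cases, and the two-sided
p-value of the ``g*e`` coefficient (Student-t, n_used - n_columns df) is
extracted.  The optional covariate-by-G and covariate-by-E product terms
follow Keller's recommendation for confounder adjustment in interaction
models and are included by default.

The module keeps a precomputed per-SNP decomposition (:class:`ScanEngine`)
so the permutation test can re-score thousands of permuted outcome
vectors without refactorizing the designs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortData

__all__ = [
    "ScanModelSpec",
    "SnpInteractionResult",
    "build_design",
    "fit_snp_interaction",
    "scan_all",
    "ScanEngine",
    "results_to_frame",
]

logger = logging.getLogger(__name__)

#: relative singular-value cutoff below which a design is rank deficient
RANK_TOL = 1e-10

STATUS_OK = "ok"
STATUS_DEGENERATE = "skipped_degenerate"


@dataclass(frozen=True)
class ScanModelSpec:
    """Model layout for the scan.

    ``keller_terms`` adds covariate-by-G and covariate-by-E products to
    the adjustment set; ``min_nonmissing`` is the smallest number of
    complete cases a SNP may have and still be fit.
    """

    exposure: str
    covariates: tuple[str, ...] = ("age", "sex")
    keller_terms: bool = True
    min_nonmissing: int = 30

    def __post_init__(self) -> None:
        if self.exposure in self.covariates:
            raise ValueError("exposure must be distinct from covariates")


@dataclass
class SnpInteractionResult:
    """OLS summary for one SNP's interaction term."""

    snp_id: str
    gene_id: str
    n_used: int
    beta_gxe: float
    se: float
    t: float
    p: float
    status: str = STATUS_OK


def build_design(
    g: np.ndarray,
    e: np.ndarray,
    covariates: dict[str, np.ndarray],
    spec: ScanModelSpec,
) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Assemble the design matrix for one SNP.

    Column order: intercept, g, e, g*e, covariates, then (with
    ``keller_terms``) covariate-by-g and covariate-by-e products.  Rows
    with any missing value are dropped (complete-case per SNP).
    Returns ``(X, column_names, used_mask)``; fewer than
    ``min_nonmissing`` complete rows raises.
    """
    g = np.asarray(g, dtype=float)
    e = np.asarray(e, dtype=float)
    cols: list[np.ndarray] = [np.ones_like(g), g, e, g * e]
    names = ["intercept", "g", "e", "g:e"]
    for name in spec.covariates:
        cols.append(np.asarray(covariates[name], dtype=float))
        names.append(name)
    if spec.keller_terms:
        for name in spec.covariates:
            c = np.asarray(covariates[name], dtype=float)
            cols.append(c * g)
            names.append(f"{name}:g")
            cols.append(c * e)
            names.append(f"{name}:e")
    X = np.column_stack(cols)
    mask = ~np.isnan(X).any(axis=1)
    if mask.sum() < spec.min_nonmissing:
        raise ValueError(
            f"only {int(mask.sum())} complete cases "
            f"(min_nonmissing={spec.min_nonmissing})"
        )
    return X[mask], names, mask


def _ols_gxe(
    X: np.ndarray, y: np.ndarray, j: int
) -> tuple[float, float, float, float]:
    """OLS via SVD; returns (beta_j, se_j, t_j, p_j) or raises on rank loss."""
    n, k = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    if s[-1] <= RANK_TOL * s[0]:
        raise np.linalg.LinAlgError("rank-deficient design")
    beta = Vt.T @ ((U.T @ y) / s)
    resid = y - X @ beta
    df = n - k
    if df <= 0:
        raise np.linalg.LinAlgError("no residual degrees of freedom")
    sigma2 = float(resid @ resid) / df
    xtx_inv_jj = float(((Vt[:, j] / s) ** 2).sum())
    se = float(np.sqrt(max(sigma2 * xtx_inv_jj, 0.0)))
    if se == 0.0:
        # noiseless fit: report an exact coefficient with p underflowing to 0
        return float(beta[j]), 0.0, np.inf, 0.0
    t = float(beta[j]) / se
    p = float(2.0 * stats.t.sf(abs(t), df))
    return float(beta[j]), se, t, max(p, 5e-324)


def fit_snp_interaction(
    y: np.ndarray,
    X: np.ndarray,
    column_names: list[str],
    snp_id: str = "",
    gene_id: str = "",
) -> SnpInteractionResult:
    """Fit one SNP's interaction model and extract the ``g:e`` term.

    A rank-deficient design (monomorphic SNP, constant exposure, ...)
    yields ``status='skipped_degenerate'`` with NaN statistics rather
    than an error, so the scan can continue.
    """
    j = column_names.index("g:e")
    y = np.asarray(y, dtype=float)
    try:
        beta, se, t, p = _ols_gxe(X, y, j)
    except np.linalg.LinAlgError:
        return SnpInteractionResult(
            snp_id, gene_id, X.shape[0], np.nan, np.nan, np.nan, np.nan,
            status=STATUS_DEGENERATE,
        )
    return SnpInteractionResult(snp_id, gene_id, X.shape[0], beta, se, t, p)


# ---------------------------------------------------------------------------
# batched engine


@dataclass
class _SnpDesign:
    snp_id: str
    gene_id: str
    mask: np.ndarray  # complete-case rows in full-cohort coordinates
    pinv: np.ndarray | None  # (k, n_used); None when degenerate
    xtx_inv_jj: float
    X: np.ndarray | None
    df: int
    j: int
    status: str


class ScanEngine:
    """Precomputed designs for scoring many outcome vectors.

    Factorizes every SNP's design once (SVD), then :meth:`scan` scores
    any sample-aligned outcome vector with two matrix products per SNP.
    Used both for the observed scan and for outcome-permutation nulls.
    """

    def __init__(self, cohort: CohortData, spec: ScanModelSpec):
        pheno = cohort.aligned_pheno()
        if spec.exposure not in pheno.columns:
            raise KeyError(f"exposure {spec.exposure!r} not in phenotype table")
        e = pheno[spec.exposure].to_numpy(dtype=float)
        covs = {c: pheno[c].to_numpy(dtype=float) for c in spec.covariates}
        gene_of = dict(zip(cohort.gene_map["snp_id"], cohort.gene_map["gene_id"]))
        self.spec = spec
        self.snp_designs: list[_SnpDesign] = []
        for snp_id in cohort.snp_ids:
            g = cohort.snp_column(snp_id)
            gene_id = gene_of.get(snp_id, "")
            try:
                X, names, mask = build_design(g, e, covs, spec)
                j = names.index("g:e")
                U, s, Vt = np.linalg.svd(X, full_matrices=False)
                if s[-1] <= RANK_TOL * s[0]:
                    raise np.linalg.LinAlgError
                df = X.shape[0] - X.shape[1]
                if df <= 0:
                    raise np.linalg.LinAlgError
                pinv = Vt.T @ np.diag(1.0 / s) @ U.T
                xtx_inv_jj = float(((Vt[:, j] / s) ** 2).sum())
                self.snp_designs.append(
                    _SnpDesign(snp_id, gene_id, mask, pinv, xtx_inv_jj, X, df, j,
                               STATUS_OK)
                )
            except (np.linalg.LinAlgError, ValueError):
                n_all = cohort.n_samples
                self.snp_designs.append(
                    _SnpDesign(snp_id, gene_id, np.zeros(n_all, bool), None,
                               np.nan, None, 0, 0, STATUS_DEGENERATE)
                )
        n_deg = sum(d.status == STATUS_DEGENERATE for d in self.snp_designs)
        if n_deg:
            logger.info("scan engine: %d degenerate SNP design(s) skipped", n_deg)

    def scan(self, y: np.ndarray) -> list[SnpInteractionResult]:
        """Score one outcome vector; one result per SNP, scan order."""
        y = np.asarray(y, dtype=float)
        out: list[SnpInteractionResult] = []
        for d in self.snp_designs:
            if d.status == STATUS_DEGENERATE:
                out.append(
                    SnpInteractionResult(d.snp_id, d.gene_id, 0, np.nan, np.nan,
                                         np.nan, np.nan, STATUS_DEGENERATE)
                )
                continue
            yy = y[d.mask]
            beta = d.pinv @ yy
            resid = yy - d.X @ beta
            sigma2 = float(resid @ resid) / d.df
            se = float(np.sqrt(max(sigma2 * d.xtx_inv_jj, 0.0)))
            b = float(beta[d.j])
            if se == 0.0:
                out.append(
                    SnpInteractionResult(d.snp_id, d.gene_id, len(yy), b, 0.0,
                                         np.inf, 0.0)
                )
                continue
            t = b / se
            p = max(float(2.0 * stats.t.sf(abs(t), d.df)), 5e-324)
            out.append(SnpInteractionResult(d.snp_id, d.gene_id, len(yy), b, se, t, p))
        return out

    def scan_pvalues(self, y: np.ndarray) -> np.ndarray:
        """Interaction p-values only (NaN for degenerate SNPs); fast path
        used inside the permutation loop."""
        y = np.asarray(y, dtype=float)
        m = len(self.snp_designs)
        t_abs = np.full(m, np.nan)
        dfs = np.zeros(m, dtype=int)
        for i, d in enumerate(self.snp_designs):
            if d.status == STATUS_DEGENERATE:
                continue
            yy = y[d.mask]
            beta = d.pinv @ yy
            resid = yy - d.X @ beta
            sigma2 = float(resid @ resid) / d.df
            se2 = sigma2 * d.xtx_inv_jj
            if se2 <= 0.0:
                t_abs[i] = np.inf
            else:
                t_abs[i] = abs(beta[d.j]) / np.sqrt(se2)
            dfs[i] = d.df
        ok = ~np.isnan(t_abs)
        p = np.full(m, np.nan)
        p[ok] = np.maximum(2.0 * stats.t.sf(t_abs[ok], dfs[ok]), 5e-324)
        return p


def scan_all(cohort: CohortData, spec: ScanModelSpec) -> list[SnpInteractionResult]:
    """Fit the interaction model for every SNP of a QC-passed cohort.

    Returns one :class:`SnpInteractionResult` per SNP in stable matrix
    order; degenerate SNPs are flagged, logged and later excluded from
    pooling.
    """
    engine = ScanEngine(cohort, spec)
    y = cohort.aligned_pheno()["symptom_score"].to_numpy(dtype=float)
    return engine.scan(y)


def results_to_frame(results: list[SnpInteractionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "gene_id": [r.gene_id for r in results],
            "n_used": [r.n_used for r in results],
            "beta": [r.beta_gxe for r in results],
            "se": [r.se for r in results],
            "t": [r.t for r in results],
            "p": [r.p for r in results],
            "status": [r.status for r in results],
        }
    )
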