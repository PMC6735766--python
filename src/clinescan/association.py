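"""Per-SNP association scans with population-structure control.

Three scan flavours share one result schema (:class:`SnpAssociation` rows):

* ``glm_scan`` — OLS of the phenotype on dosage plus covariates (PC scores);
  the reported r2 is the squared partial correlation of dosage and phenotype
  given the covariates.
* ``mlm_scan`` — single-random-effect mixed model with a genomic relationship
  matrix K, solved EMMAX-style: one spectral decomposition of K, REML of the
  variance ratio on the null model, then per-SNP GLS with those weights held
  fixed.
* ``spearman_climate_scan`` — rank correlation of dosage with a provenance
  climate value propagated to clones; rho^2 plays the role of r2.

Model choice across {simple, PC2, PC5, PC10, K, PC2+K} uses the genomic
inflation factor lambda_GC: the most parsimonious model whose lambda falls in
a configurable window (default [0.98, 1.22]) is selected.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .io_binning import VariantTable

logger = logging.getLogger(__name__)

__all__ = [
    "kinship_matrix",
    "glm_scan",
    "mlm_scan",
    "lambda_gc",
    "select_model",
    "spearman_climate_scan",
    "MODEL_PARSIMONY_ORDER",
]

CHI2_1_MEDIAN = float(stats.chi2.median(df=1))  # 0.4549364...
MODEL_PARSIMONY_ORDER = ["simple", "PC2", "PC5", "PC10", "K", "PC2+K"]


def kinship_matrix(vt: VariantTable) -> np.ndarray:
    """Centred genomic relationship matrix K = WW' / sum_m var(d_m), where
    W is the dosage matrix centred at twice the allele frequency.

    The normalizer is the summed observed dosage variance (which equals
    2*sum p(1-p) in expectation under Hardy-Weinberg), so a sample's diagonal
    entry averages 1.  Monomorphic SNPs carry no information and are skipped.
    """
    d = vt.filled_dosages()
    p = d.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("kinship undefined: all SNPs monomorphic")
    w = d[:, poly] - 2.0 * p[poly]
    denom = (w**2).sum(axis=0).sum() / d.shape[0]
    k = (w @ w.T) / denom
    return (k + k.T) / 2.0


def _scan_frame(vt, stat, p, r2, beta, trait, transect):
    return pd.DataFrame(
        {
            "snp_id": vt.snp_id,
            "chrom": vt.chrom,
            "pos": vt.pos,
            "beta": beta,
            "statistic": stat,
            "p": p,
            "r2": r2,
            "name": trait,
            "transect": transect,
        }
    )


def _partial_corr_scan(y, d, cov):
    """Residualize y and every dosage column on [1, cov]; return per-SNP
    (beta, t, p, partial r^2) with df = n - ncol([1,cov]) - 1."""
    n = y.shape[0]
    c = np.ones((n, 1)) if cov is None else np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(c) < c.shape[1]:
        raise ValueError("rank-deficient covariate matrix")
    q, _ = np.linalg.qr(c)
    ry = y - q @ (q.T @ y)
    rd = d - q @ (q.T @ d)
    df = n - c.shape[1] - 1
    if df <= 0:
        raise ValueError("not enough residual degrees of freedom")
    ss_y = float(ry @ ry)
    ss_d = (rd**2).sum(axis=0)
    xy = rd.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = xy / ss_d
        r = xy / np.sqrt(ss_d * ss_y)
    bad = ~np.isfinite(r)
    r = np.clip(np.where(bad, 0.0, r), -1.0, 1.0)
    beta = np.where(np.isfinite(beta), beta, 0.0)
    r2 = r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return beta, t, pvals, r2


def glm_scan(
    vt: VariantTable,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    name: str = "trait",
    transect: str = "",
) -> pd.DataFrame:
    """OLS association of ``phenotype`` on each SNP dosage plus covariates."""
    y = np.asarray(phenotype, dtype=float)
    if y.shape[0] != vt.n_samples:
        raise ValueError("phenotype length does not match samples")
    d = vt.filled_dosages()
    beta, t, p, r2 = _partial_corr_scan(y, d, covariates)
    return _scan_frame(vt, t, p, r2, beta, name, transect)


def _mlm_reml_neg_loglik(log_delta, lam, uy, uc):
    """-2 restricted log-likelihood of the null mixed model in rotated
    coordinates, profiled over sigma2_g; delta = sigma2_e / sigma2_g."""
    delta = np.exp(log_delta)
    n = uy.shape[0]
    w = 1.0 / (lam + delta)
    cwc = uc.T @ (w[:, None] * uc)
    cwy = uc.T @ (w * uy)
    beta = np.linalg.solve(cwc, cwy)
    r = uy - uc @ beta
    ypy = float(r @ (w * r))
    p = uc.shape[1]
    sign, logdet_cwc = np.linalg.slogdet(cwc)
    return (
        -np.log(w).sum() + logdet_cwc + (n - p) * np.log(max(ypy, 1e-300))
    )


def mlm_scan(
    vt: VariantTable,
    phenotype: np.ndarray,
    covariates: np.ndarray | None,
    K: np.ndarray,
    name: str = "trait",
    transect: str = "",
) -> pd.DataFrame:
    """Mixed-model association scan with random polygenic effect u,
    Var(u) = sigma2_g * K.

    The variance ratio is estimated once by REML on the covariate-only model
    and held fixed across SNPs; each SNP test is then a weighted least-squares
    fit in the eigenbasis of K.
    """
    y = np.asarray(phenotype, dtype=float)
    n = y.shape[0]
    if K.shape != (n, n):
        raise ValueError("K dimension does not match samples")
    lam, u = np.linalg.eigh((K + K.T) / 2.0)
    if lam.min() < -1e-8 * max(1.0, lam.max()):
        raise ValueError("K is not positive semidefinite")
    lam = np.clip(lam, 0.0, None)

    c = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates]
    )
    uy = u.T @ y
    uc = u.T @ c
    res = minimize_scalar(
        _mlm_reml_neg_loglik,
        bounds=(-12.0, 12.0),
        args=(lam, uy, uc),
        method="bounded",
        options={"xatol": 1e-8},
    )
    delta = np.exp(res.x)
    sw = np.sqrt(1.0 / (lam + delta))

    ud = u.T @ vt.filled_dosages()
    # weighted model == OLS on sqrt(w)-scaled rows; the intercept column is
    # already inside c, so residualize against the whole scaled c
    yw = sw * uy
    dw = sw[:, None] * ud
    cw = sw[:, None] * uc
    q, _ = np.linalg.qr(cw)
    ry = yw - q @ (q.T @ yw)
    rd = dw - q @ (q.T @ dw)
    df = n - c.shape[1] - 1
    ss_y = float(ry @ ry)
    ss_d = (rd**2).sum(axis=0)
    xy = rd.T @ ry
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(ss_d > 0, xy / np.where(ss_d == 0, 1, ss_d), 0.0)
        r = xy / np.sqrt(ss_d * ss_y)
    r = np.clip(np.where(np.isfinite(r), r, 0.0), -1.0, 1.0)
    r2 = r**2
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / np.maximum(1.0 - r2, 1e-300))
    pvals = np.clip(2.0 * stats.t.sf(np.abs(t), df), np.finfo(float).tiny, 1.0)
    out = _scan_frame(vt, t, pvals, r2, beta, name, transect)
    out.attrs["sigma2_g"] = float(
        (ry @ ry) / (n - c.shape[1])
    )  # profiled scale in rotated units
    out.attrs["delta"] = float(delta)
    return out


def lambda_gc(p_values) -> float:
    """Genomic inflation factor: median of the chi2(1) quantile transform of
    the p-values over the chi2(1) median."""
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1_MEDIAN)


def select_model(
    lambdas: dict[str, float], window: tuple[float, float] = (0.98, 1.22)
) -> tuple[str, bool]:
    """Most parsimonious structure model with lambda_GC inside ``window``.

    Parsimony order: simple < PC2 < PC5 < PC10 < K < PC2+K.  If no model
    qualifies, the model with lambda nearest the window is returned with an
    in-window flag of False (and a warning).
    """
    if not lambdas:
        raise ValueError("no candidate models")
    lo, hi = window
    order = [m for m in MODEL_PARSIMONY_ORDER if m in lambdas]
    order += [m for m in lambdas if m not in order]  # unknown tags last
    for m in order:
        if lo <= lambdas[m] <= hi:
            return m, True
    def dist(m):
        lam = lambdas[m]
        return lo - lam if lam < lo else lam - hi
    best = min(order, key=lambda m: (dist(m), order.index(m)))
    warnings.warn(
        f"no model with lambda_GC in [{lo}, {hi}]; "
        f"falling back to {best} (lambda={lambdas[best]:.3f})"
    )
    return best, False


def spearman_climate_scan(
    vt: VariantTable,
    climate_values: np.ndarray,
    name: str = "climate",
    transect: str = "",
) -> pd.DataFrame:
    """Spearman rank correlation of each SNP dosage with a per-sample climate
    value (provenance value propagated to its clones); midranks for ties.

    r2 column holds rho^2; p is the asymptotic two-sided t-approximation.
    """
    cv = np.asarray(climate_values, dtype=float)
    if np.nanstd(cv) == 0:
        raise ValueError("constant climate variable")
    n = vt.n_samples
    ranks_y = stats.rankdata(cv)
    ranks_d = np.apply_along_axis(stats.rankdata, 0, vt.filled_dosages())
    beta, t, p, r2 = _partial_corr_scan(ranks_y, ranks_d, None)
    rho = np.sign(beta) * np.sqrt(r2)
    out = _scan_frame(vt, rho, p, r2, beta, name, transect)
    out["statistic"] = rho
    return out
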