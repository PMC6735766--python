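"""Redundancy analysis (RDA) of the dosage matrix on climate predictors.

RDA regresses every (centred) SNP dosage on the standardized predictor
matrix and then performs a PCA of the fitted values: the constrained axes.
SNP loadings on those axes are the *locus scores*; per axis, SNPs whose score
lies more than 3 SD from the axis mean are outliers and are attributed to the
predictor their dosage correlates with most strongly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_binning import VariantTable

__all__ = ["RDAModel", "select_predictors", "fit_rda", "rda_outliers"]


@dataclass
class RDAModel:
    predictors: pd.DataFrame  # standardized, samples x p
    eigenvalues: np.ndarray  # constrained axes, non-increasing
    sample_scores: np.ndarray  # samples x axes
    locus_scores: np.ndarray  # SNPs x axes, unit-norm columns
    predictor_loadings: pd.DataFrame  # p x axes (corr of predictor with axis)
    constrained_fraction: float
    snp_ids: np.ndarray

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)


def select_predictors(
    climate: pd.DataFrame, r_max: float = 0.75, priority: list[str] | None = None
) -> list[str]:
    """Greedy collinearity pruning: walk variables in priority order, keeping
    one iff its max |Pearson r| with the kept set is below ``r_max``."""
    if climate.shape[1] < 1:
        raise ValueError("empty climate table")
    cols = list(priority) if priority else list(climate.columns)
    kept: list[str] = []
    for v in cols:
        x = climate[v].to_numpy(dtype=float)
        if np.std(x) == 0:
            continue
        ok = True
        for u in kept:
            r = np.corrcoef(x, climate[u].to_numpy(dtype=float))[0, 1]
            if abs(r) >= r_max:
                ok = False
                break
        if ok:
            kept.append(v)
    return kept


def fit_rda(vt: VariantTable, predictors: pd.DataFrame) -> RDAModel:
    """Constrained ordination: PCA of X(X'X)^-1 X' Y with Y the centred
    dosage matrix and X the z-scored predictors."""
    n = vt.n_samples
    x = predictors.to_numpy(dtype=float)
    if x.shape[0] != n:
        raise ValueError("predictor rows do not match samples")
    if x.shape[1] >= n:
        raise ValueError("need fewer predictors than samples")
    x = x - x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("constant predictor")
    x = x / sd
    if np.linalg.cond(x.T @ x) > 1e10:
        raise ValueError("collinear predictors (condition number > 1e10)")

    y = vt.filled_dosages()
    y = y - y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ beta

    u, s, vh = np.linalg.svd(fitted / np.sqrt(n - 1), full_matrices=False)
    p = x.shape[1]
    rank = min(p, int((s > s.max() * 1e-12).sum()) if s.size else 0)
    eig = s[:rank] ** 2
    sample_scores = u[:, :rank] * s[:rank]
    locus_scores = vh[:rank].T  # unit-norm columns
    # deterministic sign: largest-magnitude locus loading positive per axis
    for a in range(rank):
        jmax = np.argmax(np.abs(locus_scores[:, a]))
        if locus_scores[jmax, a] < 0:
            locus_scores[:, a] *= -1
            sample_scores[:, a] *= -1
    total = (y**2).sum() / (n - 1)
    loadings = pd.DataFrame(
        {
            f"RDA{a + 1}": [
                _safe_corr(x[:, j], sample_scores[:, a]) for j in range(p)
            ]
            for a in range(rank)
        },
        index=list(predictors.columns),
    )
    return RDAModel(
        predictors=pd.DataFrame(x, columns=predictors.columns, index=predictors.index),
        eigenvalues=eig,
        sample_scores=sample_scores,
        locus_scores=locus_scores,
        predictor_loadings=loadings,
        constrained_fraction=float(eig.sum() / total) if total > 0 else 0.0,
        snp_ids=np.asarray(vt.snp_id),
    )


def _safe_corr(a, b):
    if np.std(a) == 0 or np.std(b) == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def rda_outliers(
    model: RDAModel,
    vt: VariantTable,
    n_axes: int = 3,
    sd_mult: float = 3.0,
) -> pd.DataFrame:
    """Per-axis locus-score outliers (|score - mean| > sd_mult * SD) with each
    flagged SNP assigned to its most correlated predictor."""
    if n_axes > model.n_axes:
        raise ValueError(f"n_axes={n_axes} exceeds fitted axes ({model.n_axes})")
    d = vt.filled_dosages()
    x = model.predictors.to_numpy(dtype=float)
    pred_names = list(model.predictors.columns)
    rows = []
    for a in range(n_axes):
        sc = model.locus_scores[:, a]
        mu, sd = sc.mean(), sc.std()
        if sd == 0 or not np.isfinite(sd_mult):
            continue
        for j in np.nonzero(np.abs(sc - mu) > sd_mult * sd)[0]:
            cors = [_safe_corr(d[:, j], x[:, q]) for q in range(x.shape[1])]
            best = int(np.argmax(np.abs(cors)))
            rows.append(
                {
                    "snp_id": model.snp_ids[j],
                    "axis": a + 1,
                    "locus_score": float(sc[j]),
                    "predictor": pred_names[best],
                    "r": cors[best],
                }
            )
    return pd.DataFrame(
        rows, columns=["snp_id", "axis", "locus_score", "predictor", "r"]
    )
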