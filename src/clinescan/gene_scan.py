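"""Gene-based "top candidate" outlier test.

SNP-level association p-values are reduced to gene-level evidence: the first
percentile of SNP p-values are flagged as outliers, the expected per-gene
outlier proportion p_bar is estimated from bins with >=5 SNPs and >=1
outlier, and a bin is a *top candidate* when its outlier count strictly
exceeds the 0.999 quantile of Binomial(n_snps, p_bar).  Each bin also gets a
binomial upper-tail gene-wise p-value.  The same machinery serves phenotype
scans (GWAS p-values) and climate scans (rank-correlation p-values).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from .io_binning import GeneBin

__all__ = [
    "flag_outlier_snps",
    "count_bin_outliers",
    "expected_outlier_rate",
    "binomial_threshold",
    "scan_genes",
    "top_candidate_scan",
]


class NoEligibleBinsError(ValueError):
    """Raised when no bin has >=5 SNPs and >=1 outlier; callers may fall back
    to the global outlier fraction."""


def flag_outlier_snps(assoc: pd.DataFrame, quantile: float = 0.01) -> pd.Series:
    """Boolean flags (indexed like ``assoc``) for the ceil(quantile*M)
    smallest p-values; ties broken by smaller p then snp_id order."""
    if assoc.empty:
        raise ValueError("empty association table")
    m = len(assoc)
    n_flag = math.ceil(quantile * m)
    order = assoc.sort_values(["p", "snp_id"], kind="stable").index[:n_flag]
    flags = pd.Series(False, index=assoc.index)
    flags.loc[order] = True
    return flags


def count_bin_outliers(
    bins: list[GeneBin], assoc: pd.DataFrame, flags: pd.Series
) -> pd.DataFrame:
    """Per-bin scored-SNP and outlier counts, restricted to SNPs present in
    the association table."""
    flagged = set(assoc.loc[flags.values, "snp_id"])
    scored = set(assoc["snp_id"])
    rows = []
    for b in bins:
        in_scan = [s for s in b.snp_ids if s in scored]
        rows.append(
            {
                "bin_id": b.bin_id,
                "kind": b.kind,
                "n_snps": len(in_scan),
                "n_outliers": sum(s in flagged for s in in_scan),
            }
        )
    return pd.DataFrame(rows)


def expected_outlier_rate(bin_counts: pd.DataFrame) -> float:
    """Mean outlier proportion over eligible bins (>=5 SNPs, >=1 outlier)."""
    elig = bin_counts[(bin_counts["n_snps"] >= 5) & (bin_counts["n_outliers"] >= 1)]
    if elig.empty:
        raise NoEligibleBinsError(
            "no bin with >=5 SNPs and >=1 outlier; fall back to the global "
            "outlier fraction if an expectation is still required"
        )
    return float((elig["n_outliers"] / elig["n_snps"]).mean())


def binomial_threshold(n_snps: int, p_bar: float, q: float = 0.999) -> int:
    """Smallest integer t with P(Binomial(n_snps, p_bar) <= t) >= q."""
    if n_snps < 0 or not (0.0 <= p_bar <= 1.0):
        raise ValueError("invalid n_snps or p_bar")
    if n_snps == 0 or p_bar == 0.0:
        return 0
    return int(stats.binom.ppf(q, n_snps, p_bar))


def scan_genes(
    bin_counts: pd.DataFrame, p_bar: float, q: float = 0.999
) -> pd.DataFrame:
    """Candidate classification and gene-wise binomial p per bin.

    candidate iff n_outliers strictly exceeds the binomial q-quantile;
    gene p = P(X >= n_outliers), defined as 1 when n_outliers = 0.
    """
    n = bin_counts["n_snps"].to_numpy(dtype=int)
    k = bin_counts["n_outliers"].to_numpy(dtype=int)
    if (k > n).any():
        raise ValueError("n_outliers exceeds n_snps")
    thr = np.array([binomial_threshold(ni, p_bar, q) for ni in n])
    gene_p = np.where(k == 0, 1.0, stats.binom.sf(k - 1, np.maximum(n, 1), p_bar))
    out = bin_counts.copy()
    out["expected_rate"] = p_bar
    out["threshold"] = thr
    out["gene_p"] = gene_p
    out["candidate"] = k > thr
    return out


def top_candidate_scan(
    bins: list[GeneBin],
    assoc: pd.DataFrame,
    outlier_quantile: float = 0.01,
    binom_quantile: float = 0.999,
) -> pd.DataFrame:
    """End-to-end top-candidate scan for one trait/variable in one transect."""
    flags = flag_outlier_snps(assoc, outlier_quantile)
    counts = count_bin_outliers(bins, assoc, flags)
    p_bar = expected_outlier_rate(counts)
    return scan_genes(counts, p_bar, binom_quantile)
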