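"""End-to-end validation experiments on synthetic studies.

Each function here runs one self-contained study of the pipeline's behaviour
under known ground truth — overlap-test reproduction against published
candidate-gene counts, top-candidate calibration and sensitivity, cross-
transect null-W recovery of shared causal genes, structure-correction model
selection, and BLUP parameter recovery.  The analysis drivers and the
acceptance script are thin wrappers over these.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats

from .association import (
    glm_scan,
    kinship_matrix,
    lambda_gc,
    mlm_scan,
    select_model,
)
from .blup import fit_blups
from .gene_scan import expected_outlier_rate, scan_genes, top_candidate_scan
from .io_binning import assign_bins, filter_variants, ld_prune_sample, pca
from .parallelism import build_control_panel, hypergeom_overlap, null_z_distribution, nullw_test
from .simulate import SimulationConfig, simulate_study

__all__ = [
    "REFERENCE_OVERLAP_COUNTS",
    "reference_overlap_table",
    "topcandidate_calibration",
    "parallelism_experiment",
    "parallelism_summary",
    "structure_correction_experiment",
    "blup_recovery_experiment",
]

# Candidate-gene counts (per transect), direct-overlap counts and the bin
# universe from the published two-transect poplar exome study that this
# pipeline's overlap test is validated against.  Columns: candidates in the
# altitudinal transect (K), candidates in the latitudinal transect (n),
# direct overlap (k); universe N = 42,970 gene/intergenic bins.
REFERENCE_BIN_UNIVERSE = 42970
REFERENCE_OVERLAP_COUNTS = {
    "Height_VA": (170, 186, 2),
    "Bud set_VA": (197, 175, 4),
    "Bud flush_VA": (185, 187, 6),
    "Diameter_VA": (193, 167, 3),
    "MCMT": (215, 45, 5),
    "TD": (216, 50, 9),
    "DD_0": (190, 62, 5),
    "eFFP": (218, 63, 5),
    "MAP": (77, 110, 4),
}


def reference_overlap_table() -> pd.DataFrame:
    """Hypergeometric p-values recomputed from the published candidate counts."""
    rows = []
    for name, (K, n, k) in REFERENCE_OVERLAP_COUNTS.items():
        res = hypergeom_overlap(REFERENCE_BIN_UNIVERSE, K, n, k)
        res["name"] = name
        rows.append(res)
    return pd.DataFrame(rows)[["name", "N", "K", "n", "k", "p"]]


def topcandidate_calibration(
    seed: int,
    n_bins: int = 42970,
    mean_snps: float = 30.0,
    outlier_rate: float = 0.01,
    n_planted: int = 100,
    planted_outliers: int = 5,
) -> dict:
    """Calibration and sensitivity of the top-candidate rule on bins whose
    sizes follow a geometric law (support >= 1) with the given mean.

    Null run: exactly ceil(outlier_rate * M) SNPs flagged uniformly at random;
    reports the candidate-bin fraction.  Sensitivity run: ``n_planted`` bins
    with >= ``planted_outliers`` SNPs additionally get ``planted_outliers``
    designated outlier SNPs; reports the fraction of planted bins classified
    as candidates.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.geometric(1.0 / mean_snps, size=n_bins)
    m = int(sizes.sum())
    bin_of = np.repeat(np.arange(n_bins), sizes)
    n_flag = math.ceil(outlier_rate * m)
    flags = np.zeros(m, dtype=bool)
    flags[rng.choice(m, size=n_flag, replace=False)] = True
    k_null = np.bincount(bin_of, weights=flags, minlength=n_bins).astype(int)

    def run(k):
        counts = pd.DataFrame({"bin_id": np.arange(n_bins), "n_snps": sizes, "n_outliers": k})
        p_bar = expected_outlier_rate(counts)
        return scan_genes(counts, p_bar), p_bar

    null_scan, p_bar_null = run(k_null)
    null_fraction = float(null_scan["candidate"].mean())

    eligible = np.nonzero(sizes >= planted_outliers)[0]
    planted = rng.choice(eligible, size=n_planted, replace=False)
    flags2 = flags.copy()
    snp_start = np.concatenate([[0], np.cumsum(sizes)])
    for b in planted:
        pick = snp_start[b] + rng.choice(sizes[b], size=planted_outliers, replace=False)
        flags2[pick] = True
    k_planted = np.bincount(bin_of, weights=flags2, minlength=n_bins).astype(int)
    planted_scan, p_bar_planted = run(k_planted)
    sensitivity = float(planted_scan["candidate"].to_numpy()[planted].mean())

    return {
        "n_bins": n_bins,
        "n_snps": m,
        "p_bar_null": p_bar_null,
        "null_candidate_fraction": null_fraction,
        "p_bar_planted": p_bar_planted,
        "sensitivity": sensitivity,
    }


def _transect_scan(study, transect: str, seed: int, n_pcs: int = 0):
    """Filtered variants, clone BLUPs (VA garden) and GLM association r2/p
    for one transect of a simulated study."""
    clones = study.samples.loc[study.samples["transect"] == transect, "clone"]
    vt = filter_variants(study.variants.subset_samples(clones.tolist()))
    obs = study.phenotypes[study.phenotypes["clone"].isin(set(clones))]
    blup = fit_blups(obs, study.config.trait, "VA")
    y = blup.blups.loc[vt.samples].to_numpy()
    cov = None
    if n_pcs > 0:
        pruned = ld_prune_sample(vt, target_n=2000, seed=seed)
        cov = pca(vt, pruned, n_pcs).scores
    assoc = glm_scan(vt, y, cov, name=study.config.trait, transect=transect)
    return vt, assoc


def parallelism_experiment(seed: int, config: SimulationConfig | None = None) -> dict:
    """One full two-transect run: simulate, scan both transects, classify top
    candidates, and null-W test each transect's candidates in the other.

    Returns tallies of parallel-flagged genes split by ground-truth class
    (shared causal / transect-specific causal / non-causal).
    """
    cfg = replace(config, seed=seed) if config else SimulationConfig(seed=seed)
    study = simulate_study(cfg)
    bins = assign_bins(study.variants, study.genes)
    bin_map = {b.bin_id: b for b in bins}

    scans = {}
    for t in ("lat", "alt"):
        vt, assoc = _transect_scan(study, t, seed)
        scans[t] = {
            "assoc": assoc,
            "scores": pd.Series(assoc["r2"].to_numpy(), index=assoc["snp_id"].to_numpy()),
            "top": top_candidate_scan(bins, assoc),
        }

    out = {
        "seed": seed,
        "shared_tested": 0, "shared_parallel": 0,
        "specific_tested": 0, "specific_parallel": 0,
        "other_tested": 0, "other_parallel": 0,
    }
    shared = study.truth.shared_genes
    for a, b in (("lat", "alt"), ("alt", "lat")):
        cand_a = scans[a]["top"].loc[scans[a]["top"]["candidate"], "bin_id"].tolist()
        cand_b = set(scans[b]["top"].loc[scans[b]["top"]["candidate"], "bin_id"])
        scores_b = scans[b]["scores"]
        panel = build_control_panel(bins, cand_b, scores_b, size=10000, seed=seed)
        noncand_b = [x for x in bins if x.bin_id not in cand_b]
        null_z = null_z_distribution(noncand_b, scores_b, panel)
        res = nullw_test([bin_map[g] for g in cand_a], scores_b, panel, null_z)
        specific_a = study.truth.causal_genes[a] - shared
        for row in res.itertuples():
            if row.gene in shared:
                cls = "shared"
            elif row.gene in specific_a:
                cls = "specific"
            else:
                cls = "other"
            out[f"{cls}_tested"] += 1
            out[f"{cls}_parallel"] += int(row.parallel)
    out["n_tested"] = out["shared_tested"] + out["specific_tested"] + out["other_tested"]
    out["n_parallel"] = (
        out["shared_parallel"] + out["specific_parallel"] + out["other_parallel"]
    )
    return out


def parallelism_summary(seeds, config: SimulationConfig | None = None) -> dict:
    """Pool parallelism_experiment tallies over seeds; rates per truth class."""
    runs = [parallelism_experiment(s, config) for s in seeds]
    agg = {k: sum(r[k] for r in runs) for k in runs[0] if k != "seed"}
    agg["shared_rate"] = (
        agg["shared_parallel"] / agg["shared_tested"] if agg["shared_tested"] else np.nan
    )
    agg["specific_rate"] = (
        agg["specific_parallel"] / agg["specific_tested"]
        if agg["specific_tested"]
        else np.nan
    )
    agg["parallel_fraction"] = (
        agg["n_parallel"] / agg["n_tested"] if agg["n_tested"] else np.nan
    )
    agg["n_seeds"] = len(runs)
    return agg


NULL_STRUCTURE_CONFIG = SimulationConfig(
    n_provenances_lat=20,
    n_provenances_alt=2,
    clones_per_provenance=15,
    n_genes=400,
    snps_per_gene=12.0,
    n_intergenic_snps=2000,
    n_causal_genes_lat=0,
    n_causal_genes_alt=0,
    n_causal_shared=0,
    fst=0.15,
    env_effect_sd=0.8,
    h2_clone=0.6,
)


def structure_correction_experiment(seed: int, config: SimulationConfig | None = None) -> dict:
    """Genomic-control behaviour of the candidate structure models on a
    Balding-Nichols null study whose phenotype is confounded with provenance.

    Fits simple / PC2 / PC5 / PC10 / K / PC2+K scans on the latitudinal
    transect and returns each model's lambda_GC plus the selected model.
    """
    cfg = replace(config or NULL_STRUCTURE_CONFIG, seed=seed)
    study = simulate_study(cfg)
    clones = study.samples.loc[study.samples["transect"] == "lat", "clone"]
    vt = filter_variants(study.variants.subset_samples(clones.tolist()))
    obs = study.phenotypes[study.phenotypes["clone"].isin(set(clones))]
    blup = fit_blups(obs, cfg.trait, "VA")
    y = blup.blups.loc[vt.samples].to_numpy()

    pruned = ld_prune_sample(vt, target_n=2000, seed=seed)
    pcs = pca(vt, pruned, 10).scores
    k = kinship_matrix(vt)

    lambdas = {
        "simple": lambda_gc(glm_scan(vt, y, None)["p"]),
        "PC2": lambda_gc(glm_scan(vt, y, pcs[:, :2])["p"]),
        "PC5": lambda_gc(glm_scan(vt, y, pcs[:, :5])["p"]),
        "PC10": lambda_gc(glm_scan(vt, y, pcs)["p"]),
        "K": lambda_gc(mlm_scan(vt, y, None, k)["p"]),
        "PC2+K": lambda_gc(mlm_scan(vt, y, pcs[:, :2], k)["p"]),
    }
    selected, in_window = select_model(lambdas)
    return {
        "seed": seed,
        "lambdas": lambdas,
        "selected": selected,
        "selected_lambda": lambdas[selected],
        "in_window": bool(in_window),
    }


def blup_recovery_experiment(
    seed: int,
    n_clones: int = 200,
    n_blocks: int = 4,
    ramets_per_clone: int = 4,
    sigma2_clone: float = 1.0,
    sigma2_resid: float = 1.0,
    sigma2_block: float = 0.25,
) -> dict:
    """Parameter recovery for the block+clone REML fit on a balanced design
    (each clone's ramets spread one per block)."""
    rng = np.random.default_rng(seed)
    clones = [f"c{i:03d}" for i in range(n_clones)]
    c_eff = rng.normal(0, np.sqrt(sigma2_clone), n_clones)
    b_eff = rng.normal(0, np.sqrt(sigma2_block), n_blocks)
    rows = []
    for r in range(ramets_per_clone):
        blk = r % n_blocks
        resid = rng.normal(0, np.sqrt(sigma2_resid), n_clones)
        for j in range(n_clones):
            rows.append(
                {"clone": clones[j], "garden": "VA", "block": f"b{blk + 1}",
                 "ramet": r + 1, "trait": "height",
                 "value": 10.0 + b_eff[blk] + c_eff[j] + resid[j]}
            )
    obs = pd.DataFrame(rows)
    fit = fit_blups(obs, "height", "VA")
    blups = fit.blups.loc[clones].to_numpy()
    clone_means = obs.groupby("clone")["value"].mean().loc[clones].to_numpy()
    return {
        "seed": seed,
        "corr_blup_truth": float(np.corrcoef(blups, c_eff)[0, 1]),
        "sigma2_clone_hat": fit.sigma2_clone,
        "sigma2_resid_hat": fit.sigma2_resid,
        "variance_ratio_hat": fit.sigma2_clone / fit.sigma2_resid,
        "var_blup": float(np.var(blups)),
        "var_clone_means": float(np.var(clone_means)),
    }
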