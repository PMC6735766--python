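"""Orchestration of the full two-transect analysis.

``run_pipeline`` takes a configuration mapping (or a YAML path), executes the
requested stages — simulate (or load inputs), filter, bin, BLUP, structure-
aware GWAS, climate scans, top-candidate classification, null-W parallelism,
RDA, direct-overlap tests — and writes TSV outputs plus a JSON run log
capturing every effective parameter and seed, so a run is reproducible from
its log alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .association import (
    glm_scan,
    kinship_matrix,
    lambda_gc,
    mlm_scan,
    select_model,
    spearman_climate_scan,
)
from .blup import fit_blups
from .gene_scan import top_candidate_scan
from .io_binning import (
    assign_bins,
    bins_to_frame,
    filter_variants,
    ld_prune_sample,
    pca,
    read_genotypes,
    read_gff3_genes,
)
from .parallelism import (
    build_control_panel,
    hypergeom_overlap,
    null_z_distribution,
    nullw_test,
)
from .rda import fit_rda, rda_outliers, select_predictors
from .simulate import CLIMATE_VARIABLES, SimulationConfig, simulate_study

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline", "DEFAULT_CONFIG"]

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "out_dir": "results/pipeline",
    "simulate": {},  # SimulationConfig overrides; or use "inputs"
    "inputs": None,  # {"vcf":..., "gff3":..., "phenotypes":..., "climate":..., "samples":...}
    "filters": {"max_missing": 0.25, "min_maf": 0.05},
    "binning": {"flank": 2000, "cluster_size": 5000},
    "structure": {"pc_snps": 2000, "ld_r2_max": 0.2, "n_pcs": 10},
    "scans": {"models": ["simple", "PC2", "PC5", "PC10", "K", "PC2+K"],
              "lambda_window": [0.98, 1.22]},
    "top_candidates": {"outlier_quantile": 0.01, "binom_quantile": 0.999},
    "nullw": {"panel_size": 10000, "alpha": 0.05},
    "rda": {"n_axes": 3, "sd_mult": 3.0, "r_max": 0.75,
            "climate_variables": None},
    "climate_scan": {"variables": ["MAT", "MAP"]},
    "gardens": ["VA"],
}

_INPUT_KEYS = ("vcf", "gff3", "phenotypes", "climate", "samples")


def _merge_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh) or {}
    unknown = set(config) - set(DEFAULT_CONFIG)
    if unknown:
        raise ValueError(f"invalid config key(s): {sorted(unknown)}")
    merged = {}
    for k, v in DEFAULT_CONFIG.items():
        if isinstance(v, dict) and isinstance(config.get(k), dict):
            merged[k] = {**v, **config[k]}
        else:
            merged[k] = config.get(k, v)
    return merged


def _load_inputs(paths: dict):
    for key in _INPUT_KEYS:
        if key not in paths:
            raise ValueError(f"inputs block missing key {key!r}")
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"input file not found: {paths[key]}")
    vt = read_genotypes(paths["vcf"])
    genes = read_gff3_genes(paths["gff3"])
    phenotypes = pd.read_csv(paths["phenotypes"], sep="\t")
    climate = pd.read_csv(paths["climate"], sep="\t")
    samples = pd.read_csv(paths["samples"], sep="\t")
    return vt, genes, phenotypes, climate, samples


def _structure_models(vt, y, cfg, seed):
    """lambda_GC model selection; returns (assoc table, per-model lambdas, tag)."""
    models = cfg["scans"]["models"]
    window = tuple(cfg["scans"]["lambda_window"])
    st = cfg["structure"]
    need_pcs = any(m.startswith("PC") for m in models)
    pcs = None
    if need_pcs:
        pruned = ld_prune_sample(
            vt, r2_max=st["ld_r2_max"], target_n=st["pc_snps"], seed=seed
        )
        n_pcs = min(st["n_pcs"], vt.n_samples - 1, len(pruned))
        pcs = pca(vt, pruned, n_pcs).scores
    k = kinship_matrix(vt) if any("K" in m for m in models) else None

    def fit(tag):
        if tag == "simple":
            return glm_scan(vt, y, None)
        if tag.startswith("PC") and "+K" not in tag:
            return glm_scan(vt, y, pcs[:, : int(tag[2:])])
        if tag == "K":
            return mlm_scan(vt, y, None, k)
        if tag.endswith("+K"):
            return mlm_scan(vt, y, pcs[:, : int(tag[2:-2])], k)
        raise ValueError(f"unknown model tag {tag!r}")

    scans = {m: fit(m) for m in models}
    lambdas = {m: lambda_gc(s["p"]) for m, s in scans.items()}
    tag, in_window = select_model(lambdas, window)
    return scans[tag], lambdas, tag, in_window


def run_pipeline(config, out_dir=None) -> dict:
    """Execute the configured analysis; returns a manifest of written files.

    Raises on missing inputs or invalid configuration keys (callers running
    from a shell should map exceptions to a nonzero exit status).
    """
    cfg = _merge_config(config)
    out = Path(out_dir or cfg["out_dir"])
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    written: dict[str, str] = {}

    def emit(name, frame):
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False)
        written[name] = str(path)

    if cfg["inputs"]:
        vt_all, genes, phenotypes, climate, samples = _load_inputs(cfg["inputs"])
        trait = str(phenotypes["trait"].iloc[0])
    else:
        sim_kwargs = dict(cfg["simulate"])
        sim_kwargs.setdefault("seed", seed)
        sim_cfg = SimulationConfig(**sim_kwargs)
        study = simulate_study(sim_cfg)
        vt_all, genes = study.variants, study.genes
        phenotypes, climate, samples = study.phenotypes, study.climate, study.samples
        trait = sim_cfg.trait

    bins = assign_bins(
        vt_all, genes, flank=cfg["binning"]["flank"],
        cluster_size=cfg["binning"]["cluster_size"],
    )
    emit("bins", bins_to_frame(bins))
    bin_map = {b.bin_id: b for b in bins}
    n_universe = len(bins)

    tc = cfg["top_candidates"]
    transects = sorted(samples["transect"].unique())
    per_transect: dict[str, dict] = {}
    log: dict = {"config": cfg, "seed": seed, "version": __version__,
                 "transects": {}}

    climate_by_prov = climate.set_index("provenance")
    for t in transects:
        sub = samples[samples["transect"] == t]
        vt = filter_variants(
            vt_all.subset_samples(sub["clone"].tolist()),
            max_missing=cfg["filters"]["max_missing"],
            min_maf=cfg["filters"]["min_maf"],
        )
        tlog = {"n_snps_filtered": vt.n_snps, "n_clones": vt.n_samples}

        obs = phenotypes[phenotypes["clone"].isin(set(sub["clone"]))]
        blup = fit_blups(obs, trait, cfg["gardens"][0])
        emit(f"blups_{t}", blup.frame())
        y = blup.blups.loc[vt.samples].to_numpy()

        assoc, lambdas, tag, in_window = _structure_models(vt, y, cfg, seed)
        emit(f"gwas_{t}", assoc.drop(columns=["name", "transect"]))
        tlog.update({"lambda_gc": lambdas, "selected_model": tag,
                     "lambda_in_window": in_window})

        top = top_candidate_scan(
            bins, assoc, tc["outlier_quantile"], tc["binom_quantile"]
        )
        emit(f"top_candidates_{t}", top)

        prov_clim = climate_by_prov.loc[
            samples.set_index("clone").loc[vt.samples, "provenance"]
        ]
        gea = {}
        for v in cfg["climate_scan"]["variables"]:
            sc = spearman_climate_scan(vt, prov_clim[v].to_numpy(), name=v, transect=t)
            gea[v] = {
                "assoc": sc,
                "top": top_candidate_scan(bins, sc, tc["outlier_quantile"],
                                          tc["binom_quantile"]),
            }
            emit(f"gea_{v}_{t}", sc.drop(columns=["name", "transect"]))
            emit(f"gea_top_candidates_{v}_{t}", gea[v]["top"])

        rda_cfg = cfg["rda"]
        rda_vars = rda_cfg["climate_variables"] or [
            v for v in CLIMATE_VARIABLES if v in prov_clim.columns
        ]
        kept = select_predictors(prov_clim[rda_vars], r_max=rda_cfg["r_max"])
        model = fit_rda(vt, prov_clim[kept].reset_index(drop=True))
        n_axes = min(rda_cfg["n_axes"], model.n_axes)
        outl = rda_outliers(model, vt, n_axes=n_axes, sd_mult=rda_cfg["sd_mult"])
        emit(f"rda_eigenvalues_{t}",
             pd.DataFrame({"axis": np.arange(1, model.n_axes + 1),
                           "eigenvalue": model.eigenvalues}))
        emit(f"rda_outliers_{t}", outl)
        tlog.update({"rda_predictors": kept,
                     "rda_constrained_fraction": model.constrained_fraction})

        per_transect[t] = {"vt": vt, "assoc": assoc, "top": top, "gea": gea}
        log["transects"][t] = tlog

    # cross-transect parallelism and direct overlap (first two transects)
    if len(transects) >= 2:
        nw = cfg["nullw"]
        overlap_rows = []
        for a, b in (transects[:2], transects[:2][::-1]):
            pa, pb = per_transect[a], per_transect[b]
            scores_b = pd.Series(
                pb["assoc"]["r2"].to_numpy(), index=pb["assoc"]["snp_id"].to_numpy()
            )
            cand_a = pa["top"].loc[pa["top"]["candidate"], "bin_id"].tolist()
            cand_b = set(pb["top"].loc[pb["top"]["candidate"], "bin_id"])
            if cand_a and len(cand_b) < n_universe:
                panel = build_control_panel(
                    bins, cand_b, scores_b, size=nw["panel_size"], seed=seed
                )
                noncand = [x for x in bins if x.bin_id not in cand_b]
                null_z = null_z_distribution(noncand, scores_b, panel)
                res = nullw_test(
                    [bin_map[g] for g in cand_a], scores_b, panel, null_z,
                    alpha=nw["alpha"],
                )
                emit(f"nullw_{a}_in_{b}", res)
        a, b = transects[:2]
        ka = per_transect[a]["top"]["candidate"]
        kb = per_transect[b]["top"]["candidate"]
        set_a = set(per_transect[a]["top"].loc[ka, "bin_id"])
        set_b = set(per_transect[b]["top"].loc[kb, "bin_id"])
        row = hypergeom_overlap(
            n_universe, len(set_a), len(set_b), len(set_a & set_b)
        )
        row["name"] = trait
        overlap_rows.append(row)
        for v in cfg["climate_scan"]["variables"]:
            ga = per_transect[a]["gea"][v]["top"]
            gb = per_transect[b]["gea"][v]["top"]
            sa = set(ga.loc[ga["candidate"], "bin_id"])
            sb = set(gb.loc[gb["candidate"], "bin_id"])
            row = hypergeom_overlap(n_universe, len(sa), len(sb), len(sa & sb))
            row["name"] = v
            overlap_rows.append(row)
        emit("overlap", pd.DataFrame(overlap_rows)[["name", "N", "K", "n", "k", "p"]])

    log["outputs"] = written
    log["config_hash"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    with open(out / "run_log.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)
    written["run_log"] = str(out / "run_log.json")
    return written
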