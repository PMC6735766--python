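"""Two-transect common-garden study simulator with known ground truth.

The generator emulates the design the downstream scans assume: clones sampled
from provenances along a latitudinal and an altitudinal transect, genotyped
at SNPs housed in annotated genes (plus intergenic SNPs), phenotyped as
replicated ramets in randomized blocks in two common gardens, with climate
summarised per provenance.

Population structure follows a Balding-Nichols model: each SNP has an
ancestral frequency p0 ~ U(0.05, 0.95) and every provenance draws its own
frequency from Beta(p0(1-F)/F, (1-p0)(1-F)/F).  Causal SNPs additionally
follow a linear cline in latitude (latitudinal transect) or elevation
(altitudinal transect); genes shared between transects are clinal — with the
same allele-effect orientation — in both.  Climate variables are affine
functions of the transect gradient plus independent noise, so they carry the
correlation structure the genotype-environment scans rely on without
modelling any real climate surface.

Phenotype observations are

    y = grand mean + block effect + clone value + residual,

where the clone value sums causal-SNP effects and a provenance-level
environmental term, and the residual SD is set so the clone-level
repeatability matches ``h2_clone``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_binning import VariantTable

__all__ = ["SimulationConfig", "SimulationTruth", "Study", "simulate_study", "write_study"]

CLIMATE_VARIABLES = [
    "MAT", "MWMT", "MCMT", "TD", "MAP", "MSP", "AHM", "SHM",
    "DD_0", "DD5", "DD_18", "DD18", "NFFD", "FFP", "bFFP", "eFFP",
    "PAS", "EMT", "EXT", "Eref", "CMD",
]


@dataclass
class SimulationConfig:
    """Study-design knobs.  Defaults mirror the motivating design: ~480 clones
    over 68 latitudinal (4 clones each) + 13 altitudinal provenances (13
    clones each), 4 ramets in 4 blocks in each of 2 gardens, ~40k SNPs in
    2,000 genes plus intergenic clusters."""

    n_provenances_lat: int = 68
    n_provenances_alt: int = 13
    clones_per_provenance: int = 4
    clones_per_provenance_alt: int | None = 13  # None = same as latitudinal
    n_gardens: int = 2
    n_blocks: int = 4
    ramets_per_clone: int = 4
    n_genes: int = 2000
    snps_per_gene: float = 18.0
    n_intergenic_snps: int = 4000
    fst: float = 0.15
    n_causal_genes_lat: int = 20
    n_causal_genes_alt: int = 20
    n_causal_shared: int = 10
    effect_size_sd: float = 0.3
    h2_clone: float = 0.6
    climate_noise_sd: float = 0.3
    env_effect_sd: float = 0.5
    cline_slope: float = 0.35
    causal_snps_per_gene: int = 5
    missing_rate: float = 0.0
    trait: str = "height"
    seed: int = 1

    def validate(self) -> None:
        structural = [
            self.n_provenances_lat, self.n_provenances_alt,
            self.clones_per_provenance, self.n_gardens, self.n_blocks,
            self.ramets_per_clone, self.n_genes,
        ]
        if any(c <= 0 for c in structural):
            raise ValueError("structural design counts must be > 0")
        if not (0.0 < self.fst < 1.0):
            raise ValueError("fst must be in (0, 1)")
        if not (0.0 < self.h2_clone <= 1.0):
            raise ValueError("h2_clone must be in (0, 1]")
        if min(self.n_causal_genes_lat, self.n_causal_genes_alt,
               self.n_causal_shared, self.n_intergenic_snps) < 0:
            raise ValueError("causal/intergenic counts must be >= 0")
        if self.n_causal_shared > min(self.n_causal_genes_lat, self.n_causal_genes_alt):
            raise ValueError("n_causal_shared exceeds a transect's causal-gene count")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SimulationTruth:
    causal_snps: dict  # transect -> list of (snp_id, effect)
    causal_genes: dict  # transect -> set of gene ids
    shared_genes: set
    provenance_positions: pd.DataFrame
    true_clone_values: pd.Series


@dataclass
class Study:
    variants: VariantTable
    genes: pd.DataFrame  # gene_id, chrom, start, end
    phenotypes: pd.DataFrame  # clone, garden, block, ramet, trait, value
    climate: pd.DataFrame  # provenance, latitude, longitude, elevation, 21 vars
    samples: pd.DataFrame  # clone, transect, provenance, latitude, longitude, elevation
    truth: SimulationTruth
    config: SimulationConfig = field(repr=False, default=None)


def _layout_genome(cfg: SimulationConfig, rng) -> tuple[pd.DataFrame, list]:
    """Place genes on chromosomes with gaps wide enough that flanked spans
    never merge and every gap hosts a >=2 kb interior free of gene flanks."""
    n_chrom = min(19, cfg.n_genes)
    genes = []
    gaps = []  # (chrom, lo, hi) interiors >2 kb from any gene
    per = np.full(n_chrom, cfg.n_genes // n_chrom)
    per[: cfg.n_genes % n_chrom] += 1
    gi = 0
    for c in range(n_chrom):
        ch = f"chr{c + 1:02d}"
        cur = 0
        prev_end = None
        for _ in range(per[c]):
            gap = int(rng.integers(6001, 20001))
            length = int(rng.integers(2000, 5001))
            start = cur + gap
            end = start + length - 1
            genes.append({"gene_id": f"g{gi:05d}", "chrom": ch, "start": start, "end": end})
            if prev_end is not None:
                lo, hi = prev_end + 2001, start - 2001
                if hi - lo >= 100:
                    gaps.append((ch, lo, hi))
            prev_end = end
            cur = end
            gi += 1
        if prev_end is not None:  # tail gap after the last gene
            gaps.append((ch, prev_end + 2001, prev_end + 22000))
    return pd.DataFrame(genes), gaps


def _place_snps(cfg: SimulationConfig, genes: pd.DataFrame, gaps, rng):
    """Return (chrom, pos, gene_of_snp) arrays; intergenic SNPs have gene None."""
    chrom, pos, owner = [], [], []
    for row in genes.itertuples():
        span = row.end - row.start + 1
        k = max(1, int(rng.poisson(cfg.snps_per_gene)))
        k = min(k, span)
        offsets = rng.choice(span, size=k, replace=False)
        for o in np.sort(offsets):
            chrom.append(row.chrom)
            pos.append(row.start + int(o))
            owner.append(row.gene_id)
    if cfg.n_intergenic_snps > 0:
        if not gaps:
            raise ValueError("no intergenic room for requested intergenic SNPs")
        lens = np.array([hi - lo + 1 for _, lo, hi in gaps], dtype=float)
        which = rng.choice(len(gaps), size=cfg.n_intergenic_snps, p=lens / lens.sum())
        for gidx in which:
            ch, lo, hi = gaps[gidx]
            chrom.append(ch)
            pos.append(int(rng.integers(lo, hi + 1)))
            owner.append(None)
    df = pd.DataFrame({"chrom": chrom, "pos": pos, "owner": owner})
    df = (
        df.drop_duplicates(["chrom", "pos"])
        .sort_values(["chrom", "pos"], kind="stable")
        .reset_index(drop=True)
    )
    df["snp_id"] = [f"s{i:06d}" for i in range(len(df))]
    return df


def simulate_study(config: SimulationConfig) -> Study:
    """Generate a complete two-transect study; identical seeds give
    bit-identical outputs."""
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes, gaps = _layout_genome(cfg, rng)
    snps = _place_snps(cfg, genes, gaps, rng)
    m = len(snps)

    # provenances and transect gradient positions z in [-1, 1]
    def grad(x):
        x = np.asarray(x, dtype=float)
        if x.max() == x.min():
            return np.zeros_like(x)
        return 2.0 * (x - x.min()) / (x.max() - x.min()) - 1.0

    lat_latitudes = np.linspace(44.0, 59.6, cfg.n_provenances_lat)
    alt_elevations = np.linspace(150.0, 1500.0, cfg.n_provenances_alt)
    prov_rows = []
    for i, la in enumerate(lat_latitudes):
        prov_rows.append(
            {"provenance": f"L{i:02d}", "transect": "lat", "latitude": la,
             "longitude": -122.0 + rng.normal(0, 1.5),
             "elevation": float(rng.uniform(0, 300))}
        )
    for i, el in enumerate(alt_elevations):
        prov_rows.append(
            {"provenance": f"A{i:02d}", "transect": "alt",
             "latitude": 49.9 + rng.normal(0, 0.2),
             "longitude": -121.5 + rng.normal(0, 0.8),
             "elevation": float(el)}
        )
    prov = pd.DataFrame(prov_rows)
    z = np.where(
        prov["transect"] == "lat",
        np.concatenate([grad(lat_latitudes), np.zeros(cfg.n_provenances_alt)]),
        np.concatenate([np.zeros(cfg.n_provenances_lat), grad(alt_elevations)]),
    )
    prov["z"] = z
    n_prov = len(prov)

    # Balding-Nichols provenance allele frequencies
    p0 = rng.uniform(0.05, 0.95, size=m)
    f = cfg.fst
    a = p0 * (1 - f) / f
    b = (1 - p0) * (1 - f) / f
    p_prov = rng.beta(a[None, :], b[None, :], size=(n_prov, m))

    # causal genes: shared first, then transect-specific (disjoint)
    gene_ids = genes["gene_id"].tolist()
    n_needed = (cfg.n_causal_genes_lat + cfg.n_causal_genes_alt - cfg.n_causal_shared)
    if n_needed > len(gene_ids):
        raise ValueError("not enough genes for requested causal counts")
    picked = rng.choice(len(gene_ids), size=n_needed, replace=False)
    shared = [gene_ids[i] for i in picked[: cfg.n_causal_shared]]
    lat_only = [
        gene_ids[i]
        for i in picked[cfg.n_causal_shared : cfg.n_causal_genes_lat]
    ]
    alt_only = [gene_ids[i] for i in picked[cfg.n_causal_genes_lat :]]
    causal_genes = {"lat": set(shared) | set(lat_only), "alt": set(shared) | set(alt_only)}

    by_owner = snps.groupby("owner")["snp_id"].apply(list)
    snp_index = {s: i for i, s in enumerate(snps["snp_id"])}
    lat_mask = (prov["transect"] == "lat").to_numpy()
    alt_mask = ~lat_mask

    causal_snps = {"lat": [], "alt": []}

    def plant(gene_id, transects):
        # every SNP of a causal gene tracks the cline (emulating LD with the
        # selected variant: one coherent direction per gene, per-SNP magnitude);
        # trait effects sit on a subset of them
        ids = by_owner.get(gene_id, [])
        if not ids:
            return
        gene_sign = 1 if rng.random() < 0.5 else -1
        k = min(cfg.causal_snps_per_gene, len(ids))
        effect_ids = set(rng.choice(len(ids), size=k, replace=False).tolist())
        for i, s in enumerate(ids):
            j = snp_index[s]
            slope = gene_sign * cfg.cline_slope * rng.uniform(0.6, 1.0)
            # directional selection: the allele rising along the gradient
            # increases the trait, so every causal gene reinforces the cline
            eff = (
                gene_sign * abs(rng.normal(0, cfg.effect_size_sd))
                if i in effect_ids
                else None
            )
            for t in transects:
                tmask = lat_mask if t == "lat" else alt_mask
                p_prov[tmask, j] = np.clip(
                    p_prov[tmask, j] + slope * prov.loc[tmask, "z"].to_numpy(),
                    0.02, 0.98,
                )
                if eff is not None:
                    causal_snps[t].append((s, eff))

    for g in shared:
        plant(g, ("lat", "alt"))
    for g in lat_only:
        plant(g, ("lat",))
    for g in alt_only:
        plant(g, ("alt",))

    # clones and genotypes
    cpp_alt = (
        cfg.clones_per_provenance_alt
        if cfg.clones_per_provenance_alt is not None
        else cfg.clones_per_provenance
    )
    clone_rows = []
    for _, pr in prov.iterrows():
        n_cl = cfg.clones_per_provenance if pr.transect == "lat" else cpp_alt
        for c in range(n_cl):
            clone_rows.append(
                {"clone": f"{pr.provenance}-c{c:02d}", "transect": pr.transect,
                 "provenance": pr.provenance, "latitude": pr.latitude,
                 "longitude": pr.longitude, "elevation": pr.elevation}
            )
    samples = pd.DataFrame(clone_rows)
    prov_codes = prov.reset_index().set_index("provenance")["index"]
    codes = prov_codes.loc[samples["provenance"]].to_numpy()
    dos = rng.binomial(2, p_prov[codes, :]).astype(float)
    if cfg.missing_rate > 0:
        miss = rng.random(dos.shape) < cfg.missing_rate
        dos[miss] = np.nan

    variants = VariantTable(
        snp_id=snps["snp_id"].to_numpy(dtype=object),
        chrom=snps["chrom"].to_numpy(dtype=object),
        pos=snps["pos"].to_numpy(dtype=int),
        ref=np.full(m, "A", dtype=object),
        alt=np.full(m, "G", dtype=object),
        dosages=dos,
        samples=samples["clone"].tolist(),
    )

    # climate: affine in the transect gradient + independent noise
    clim = {"provenance": prov["provenance"], "latitude": prov["latitude"],
            "longitude": prov["longitude"], "elevation": prov["elevation"]}
    for v in CLIMATE_VARIABLES:
        load = rng.uniform(0.6, 1.0) * (1 if rng.random() < 0.5 else -1)
        clim[v] = load * prov["z"].to_numpy() + rng.normal(
            0, cfg.climate_noise_sd, size=n_prov
        )
    climate = pd.DataFrame(clim)

    # clone values: causal effects + provenance environmental term
    eff_by_snp: dict[str, float] = {}
    for t in ("lat", "alt"):
        for s, e in causal_snps[t]:
            eff_by_snp[s] = e  # shared SNPs: same effect both transects
    g_val = np.zeros(len(samples))
    if eff_by_snp:
        idx = [snp_index[s] for s in eff_by_snp]
        evec = np.array(list(eff_by_snp.values()))
        g_val = np.nan_to_num(dos[:, idx]) @ evec
    z_clone = prov.set_index("provenance")["z"].loc[samples["provenance"]].to_numpy()
    clone_val = g_val + cfg.env_effect_sd * z_clone
    sd_c = clone_val.std()
    if sd_c == 0:
        sd_c = 1.0
    sigma_e = 0.0 if cfg.h2_clone >= 1.0 else sd_c * np.sqrt(
        (1 - cfg.h2_clone) / cfg.h2_clone
    )

    gardens = ["VA", "BC"][: cfg.n_gardens] + [
        f"G{i}" for i in range(3, cfg.n_gardens + 1)
    ]
    mu = 10.0
    ph_rows = []
    n_clones = len(samples)
    for gd in gardens:
        block_eff = rng.normal(0, 0.5 * sd_c, size=cfg.n_blocks)
        for r in range(cfg.ramets_per_clone):
            blk = r % cfg.n_blocks
            resid = rng.normal(0, sigma_e, size=n_clones) if sigma_e > 0 else np.zeros(n_clones)
            ph_rows.append(
                pd.DataFrame(
                    {"clone": samples["clone"], "garden": gd,
                     "block": f"b{blk + 1}", "ramet": r + 1,
                     "trait": cfg.trait,
                     "value": mu + block_eff[blk] + clone_val + resid}
                )
            )
    phenotypes = pd.concat(ph_rows, ignore_index=True)

    truth = SimulationTruth(
        causal_snps=causal_snps,
        causal_genes=causal_genes,
        shared_genes=set(shared),
        provenance_positions=prov[["provenance", "transect", "latitude",
                                   "elevation", "z"]].copy(),
        true_clone_values=pd.Series(clone_val, index=samples["clone"].to_numpy()),
    )
    return Study(variants=variants, genes=genes, phenotypes=phenotypes,
                 climate=climate, samples=samples, truth=truth, config=cfg)


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def write_study(study: Study, out_dir) -> dict:
    """Write genotypes (VCFv4.2), annotation (GFF3), phenotype/climate/sample
    TSVs and the ground truth (JSON); returns the path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    vt = study.variants

    vcf_path = out / "genotypes.vcf"
    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for ch in pd.unique(vt.chrom):
            fh.write(f"##contig=<ID={ch}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(vt.samples) + "\n"
        )
        d = vt.dosages
        for j in range(vt.n_snps):
            gts = "\t".join(
                "./." if np.isnan(d[i, j]) else _GT[d[i, j]]
                for i in range(vt.n_samples)
            )
            fh.write(
                f"{vt.chrom[j]}\t{vt.pos[j]}\t{vt.snp_id[j]}\t{vt.ref[j]}\t"
                f"{vt.alt[j]}\t.\tPASS\t.\tGT\t{gts}\n"
            )

    gff_path = out / "genes.gff3"
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in study.genes.itertuples():
            fh.write(
                f"{row.chrom}\tsim\tgene\t{row.start}\t{row.end}\t.\t+\t.\t"
                f"ID={row.gene_id}\n"
            )

    pheno_path = out / "phenotypes.tsv"
    study.phenotypes.to_csv(pheno_path, sep="\t", index=False)
    climate_path = out / "climate.tsv"
    study.climate.to_csv(climate_path, sep="\t", index=False)
    samples_path = out / "samples.tsv"
    study.samples.to_csv(samples_path, sep="\t", index=False)

    truth_path = out / "truth.json"
    t = study.truth
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "causal_snps": {k: [[s, float(e)] for s, e in v]
                                for k, v in t.causal_snps.items()},
                "causal_genes": {k: sorted(v) for k, v in t.causal_genes.items()},
                "shared_genes": sorted(t.shared_genes),
                "true_clone_values": {k: float(v)
                                      for k, v in t.true_clone_values.items()},
                "config": asdict(study.config) if study.config else None,
            },
            fh, indent=1,
        )
    return {"vcf": vcf_path, "gff3": gff_path, "phenotypes": pheno_path,
            "climate": climate_path, "samples": samples_path, "truth": truth_path}
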