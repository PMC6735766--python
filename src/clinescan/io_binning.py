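"""Genotype / annotation I/O, variant filtering, SNP-to-gene binning and
population-structure helpers.

The unit of all downstream gene-based scans is the *bin*: a gene body extended
by a flank on both sides (default 2 kb), or — for SNPs outside any gene
neighbourhood — a 5-kb window tiled across the maximal gene-free interval that
contains them.  Every retained SNP belongs to exactly one bin.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

__all__ = [
    "VariantTable",
    "GeneBin",
    "PcaResult",
    "read_genotypes",
    "read_gff3_genes",
    "filter_variants",
    "assign_bins",
    "ld_prune_sample",
    "pca",
]


@dataclass
class VariantTable:
    """Biallelic SNP dosage matrix with per-SNP summaries.

    ``dosages`` is samples x SNPs, entries 0/1/2 (alt-allele count) or NaN for
    missing.  ``maf``/``missingness`` are recomputed from the matrix on
    construction so they can never drift out of sync.
    """

    snp_id: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray  # 1-based
    ref: np.ndarray
    alt: np.ndarray
    dosages: np.ndarray
    samples: list[str]
    maf: np.ndarray = field(init=False)
    missingness: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.samples), len(self.snp_id)):
            raise ValueError(
                f"dosage matrix {self.dosages.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snp_id)} SNPs"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
            p = np.nanmean(self.dosages, axis=0) / 2.0
        self.maf = np.where(np.isnan(p), 0.0, np.minimum(p, 1.0 - p))
        self.missingness = np.isnan(self.dosages).mean(axis=0)

    @property
    def n_snps(self) -> int:
        return len(self.snp_id)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def subset_samples(self, sample_ids) -> "VariantTable":
        idx = [self.samples.index(s) for s in sample_ids]
        return VariantTable(
            snp_id=self.snp_id,
            chrom=self.chrom,
            pos=self.pos,
            ref=self.ref,
            alt=self.alt,
            dosages=self.dosages[idx, :],
            samples=list(sample_ids),
        )

    def subset_snps(self, mask_or_index) -> "VariantTable":
        m = np.asarray(mask_or_index)
        return VariantTable(
            snp_id=self.snp_id[m],
            chrom=self.chrom[m],
            pos=self.pos[m],
            ref=self.ref[m],
            alt=self.alt[m],
            dosages=self.dosages[:, m],
            samples=list(self.samples),
        )

    def filled_dosages(self) -> np.ndarray:
        """Dosage matrix with missing entries replaced by the per-SNP mean."""
        d = self.dosages
        if not np.isnan(d).any():
            return d
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        out = d.copy()
        nan_r, nan_c = np.nonzero(np.isnan(d))
        out[nan_r, nan_c] = col_mean[nan_c]
        return out


@dataclass(frozen=True)
class GeneBin:
    """A genic (gene body + flanks) or intergenic-cluster interval owning SNPs."""

    bin_id: str
    kind: str  # "genic" | "intergenic_cluster"
    chrom: str
    start: int  # 1-based inclusive, flanks included for genic bins
    end: int
    snp_ids: tuple

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)


@dataclass(frozen=True)
class PcaResult:
    scores: np.ndarray  # samples x k
    explained_variance_ratio: np.ndarray
    snp_ids: tuple


def read_genotypes(vcf_path) -> VariantTable:
    """Read a VCFv4.2 into a :class:`VariantTable`.

    Dosage is the alt-allele count from GT.  Non-biallelic records are dropped
    and half-calls set to missing; both are counted and logged as warnings.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"no samples in {vcf_path}")

    snp_id, chrom, pos, ref, alt, cols = [], [], [], [], [], []
    n_multiallelic = 0
    n_halfcall = 0
    for v in vcf:
        if len(v.ALT) != 1 or len(v.REF) != 1 or len(v.ALT[0]) != 1:
            n_multiallelic += 1
            continue
        # gts012: 0/1/2 = alt count, 3 = unknown (missing or half-call)
        g = v.gt_types.astype(float)
        unknown = g == 3
        if unknown.any():
            # distinguish true ./. from half-calls for the warning counter
            alleles = np.asarray(v.genotypes, dtype=object)
            for i in np.nonzero(unknown)[0]:
                a = alleles[i][:-1]
                if any(x >= 0 for x in a) and any(x < 0 for x in a):
                    n_halfcall += 1
            g[unknown] = np.nan
        snp_id.append(v.ID if v.ID not in (None, ".") else f"{v.CHROM}:{v.POS}")
        chrom.append(v.CHROM)
        pos.append(v.POS)
        ref.append(v.REF)
        alt.append(v.ALT[0])
        cols.append(g)
    if n_multiallelic:
        logger.warning("dropped %d non-biallelic records", n_multiallelic)
    if n_halfcall:
        logger.warning("set %d half-called genotypes to missing", n_halfcall)

    dosages = (
        np.column_stack(cols) if cols else np.empty((len(samples), 0))
    )
    vt = VariantTable(
        snp_id=np.asarray(snp_id, dtype=object),
        chrom=np.asarray(chrom, dtype=object),
        pos=np.asarray(pos, dtype=int),
        ref=np.asarray(ref, dtype=object),
        alt=np.asarray(alt, dtype=object),
        dosages=dosages,
        samples=samples,
    )
    vt.n_rejected_multiallelic = n_multiallelic
    vt.n_halfcalls = n_halfcall
    return vt


def read_gff3_genes(gff_path) -> pd.DataFrame:
    """Gene features from a GFF3 as a DataFrame (gene_id, chrom, start, end)."""
    import gffutils
    from gffutils.exceptions import EmptyInputError

    try:
        db = gffutils.create_db(
            str(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except EmptyInputError:
        return pd.DataFrame(columns=["gene_id", "chrom", "start", "end"])
    rows = [
        {
            "gene_id": g.attributes.get("ID", [g.id])[0],
            "chrom": g.seqid,
            "start": g.start,
            "end": g.end,
        }
        for g in db.features_of_type("gene")
    ]
    genes = pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])
    return genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def filter_variants(
    vt: VariantTable, max_missing: float = 0.25, min_maf: float = 0.05
) -> VariantTable:
    """Retain SNPs with missingness < ``max_missing`` and MAF > ``min_maf``
    (both strict); fill remaining missing dosages with the per-SNP mean."""
    keep = (vt.missingness < max_missing) & (vt.maf > min_maf)
    logger.info("filter_variants: kept %d of %d SNPs", int(keep.sum()), vt.n_snps)
    out = vt.subset_snps(keep)
    return replace_dosages(out, out.filled_dosages())


def replace_dosages(vt: VariantTable, dosages: np.ndarray) -> VariantTable:
    return VariantTable(
        snp_id=vt.snp_id,
        chrom=vt.chrom,
        pos=vt.pos,
        ref=vt.ref,
        alt=vt.alt,
        dosages=dosages,
        samples=list(vt.samples),
    )


def _genic_assignment(pos, tree) -> int | None:
    """Index of the owning gene for a position, or None if outside all flanks.

    Among genes whose flanked span covers ``pos``, pick the one with the
    nearest gene-body boundary (distance 0 inside the body); ties go to the
    gene with the lower start coordinate.
    """
    hits = tree[pos]
    if not hits:
        return None
    best = None
    for iv in hits:
        start, end, gi = iv.data
        dist = max(start - pos, pos - end, 0)
        key = (dist, start)
        if best is None or key < best[0]:
            best = (key, gi)
    return best[1]


def assign_bins(
    vt: VariantTable,
    genes: pd.DataFrame,
    flank: int = 2000,
    cluster_size: int = 5000,
) -> list[GeneBin]:
    """Partition SNPs into gene bins (body ± ``flank``) and 5-kb intergenic
    clusters tiled from the start of each maximal gene-free interval.

    Returns only non-empty bins; every SNP lands in exactly one bin.
    """
    genes = genes.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    bins: dict[str, dict] = {}
    vt_chroms = set(vt.chrom.tolist())
    gene_chroms = set(genes["chrom"].tolist())
    orphan = vt_chroms - gene_chroms
    if orphan and len(genes):
        logger.warning(
            "%d chromosome(s) with SNPs but no annotation; SNPs go to clusters",
            len(orphan),
        )

    for ch in sorted(vt_chroms):
        sub = genes[genes["chrom"] == ch]
        tree = IntervalTree()
        spans = []
        for gi, row in sub.iterrows():
            lo = max(1, int(row.start) - flank)
            hi = int(row.end) + flank
            tree[lo : hi + 1] = (int(row.start), int(row.end), gi)
            spans.append((lo, hi))
        # merged flanked spans -> maximal gene-free intervals between them
        merged = []
        for lo, hi in sorted(spans):
            if merged and lo <= merged[-1][1] + 1:
                merged[-1][1] = max(merged[-1][1], hi)
            else:
                merged.append([lo, hi])
        free_starts = [1] + [hi + 1 for _, hi in merged]

        snp_idx = np.nonzero(vt.chrom == ch)[0]
        for j in snp_idx:
            p = int(vt.pos[j])
            gi = _genic_assignment(p, tree)
            if gi is not None:
                row = genes.loc[gi]
                bid = str(row.gene_id)
                b = bins.setdefault(
                    bid,
                    {
                        "kind": "genic",
                        "chrom": ch,
                        "start": max(1, int(row.start) - flank),
                        "end": int(row.end) + flank,
                        "snps": [],
                    },
                )
            else:
                # find the gene-free interval containing p
                istart = 1
                for s in free_starts:
                    if s <= p:
                        istart = s
                    else:
                        break
                w = (p - istart) // cluster_size
                wlo = istart + w * cluster_size
                whi = wlo + cluster_size - 1
                bid = f"cluster:{ch}:{wlo}-{whi}"
                b = bins.setdefault(
                    bid,
                    {
                        "kind": "intergenic_cluster",
                        "chrom": ch,
                        "start": wlo,
                        "end": whi,
                        "snps": [],
                    },
                )
            b["snps"].append(vt.snp_id[j])

    return [
        GeneBin(
            bin_id=bid,
            kind=b["kind"],
            chrom=b["chrom"],
            start=b["start"],
            end=b["end"],
            snp_ids=tuple(b["snps"]),
        )
        for bid, b in bins.items()
    ]


def bins_to_frame(bins: list[GeneBin]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "bin_id": [b.bin_id for b in bins],
            "kind": [b.kind for b in bins],
            "chrom": [b.chrom for b in bins],
            "start": [b.start for b in bins],
            "end": [b.end for b in bins],
            "n_snps": [b.n_snps for b in bins],
        }
    )


def ld_prune_sample(
    vt: VariantTable,
    r2_max: float = 0.2,
    target_n: int = 10000,
    seed: int = 0,
    window: int = 100,
) -> list:
    """Seeded greedy LD pruning: scan SNPs in random order, keep a SNP if its
    squared Pearson correlation with each of the last ``window`` kept SNPs on
    the same chromosome is below ``r2_max``; stop at ``target_n``.
    """
    if vt.n_snps < 2:
        return list(vt.snp_id)
    d = vt.filled_dosages()
    z = d - d.mean(axis=0)
    norm = np.sqrt((z**2).sum(axis=0))
    nonconst = norm > 0
    z = np.where(nonconst, z / np.where(norm == 0, 1.0, norm), 0.0)

    rng = np.random.default_rng(seed)
    order = rng.permutation(vt.n_snps)
    kept: list[int] = []
    kept_by_chrom: dict[str, list[int]] = {}
    for j in order:
        ch = vt.chrom[j]
        recent = kept_by_chrom.get(ch, [])[-window:]
        if recent:
            r2 = (z[:, recent].T @ z[:, j]) ** 2
            if (r2 >= r2_max).any():
                continue
        kept.append(j)
        kept_by_chrom.setdefault(ch, []).append(j)
        if len(kept) >= target_n:
            break
    return [vt.snp_id[j] for j in kept]


def pca(vt: VariantTable, snp_ids, k: int) -> PcaResult:
    """PCA of the centred (unscaled) dosage matrix restricted to ``snp_ids``.

    Component signs are fixed so each component's largest-magnitude SNP
    loading is positive.
    """
    id_to_col = {s: i for i, s in enumerate(vt.snp_id)}
    cols = [id_to_col[s] for s in snp_ids]
    x = vt.filled_dosages()[:, cols]
    if k > min(x.shape[0] - 1, x.shape[1]):
        raise ValueError(f"k={k} exceeds min(n_samples-1, n_snps)")
    xc = x - x.mean(axis=0)
    u, s, vtm = np.linalg.svd(xc, full_matrices=False)
    total = (xc**2).sum()
    scores = u[:, :k] * s[:k]
    loadings = vtm[:k]
    for i in range(k):
        jmax = np.argmax(np.abs(loadings[i]))
        if loadings[i, jmax] < 0:
            loadings[i] *= -1
            scores[:, i] *= -1
    evr = (s[:k] ** 2) / total if total > 0 else np.zeros(k)
    return PcaResult(
        scores=scores, explained_variance_ratio=evr, snp_ids=tuple(snp_ids)
    )
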