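#!/usr/bin/env python
"""LD-pruned PCA of each transect: the structure covariates for the scans.

Writes per-transect PC scores and explained-variance fractions under
results/02_structure/ and reports how much variance the leading axes carry.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import load_study, out_dir
from clinescan.io_binning import filter_variants, ld_prune_sample, pca

OUT = out_dir("02_structure")
vt_all, genes, phenotypes, climate, samples = load_study()

for t in ("lat", "alt"):
    clones = samples.loc[samples["transect"] == t, "clone"].tolist()
    vt = filter_variants(vt_all.subset_samples(clones))
    pruned = ld_prune_sample(vt, r2_max=0.2, target_n=2000, seed=1)
    k = min(10, vt.n_samples - 1, len(pruned))
    res = pca(vt, pruned, k)
    scores = pd.DataFrame(res.scores, columns=[f"PC{i+1}" for i in range(k)])
    scores.insert(0, "clone", vt.samples)
    scores.to_csv(OUT / f"pca_scores_{t}.tsv", sep="\t", index=False)
    pd.DataFrame({"PC": range(1, k + 1),
                  "explained": res.explained_variance_ratio}).to_csv(
        OUT / f"pca_variance_{t}.tsv", sep="\t", index=False)
    print(f"{t}: {vt.n_snps} filtered SNPs, {len(pruned)} pruned for PCA; "
          f"PC1 {res.explained_variance_ratio[0]:.1%}, "
          f"PC1-5 {res.explained_variance_ratio[:5].sum():.1%} of variance")
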