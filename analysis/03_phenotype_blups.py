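#!/usr/bin/env python
"""Clone BLUPs per garden from the replicated randomized-block phenotypes.

Writes results/03_blups/blups.tsv and reports variance components and the
realized clone-level repeatability for each garden.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import load_study, out_dir
from clinescan.blup import fit_blups

OUT = out_dir("03_blups")
_, _, phenotypes, _, _ = load_study()

frames = []
for garden in sorted(phenotypes["garden"].unique()):
    for trait in sorted(phenotypes["trait"].unique()):
        fit = fit_blups(phenotypes, trait, garden)
        frames.append(fit.frame())
        h2 = fit.sigma2_clone / (fit.sigma2_clone + fit.sigma2_resid)
        print(f"{trait}_{garden}: mu={fit.grand_mean:.3f} "
              f"s2_block={fit.sigma2_block:.3f} s2_clone={fit.sigma2_clone:.3f} "
              f"s2_resid={fit.sigma2_resid:.3f} repeatability={h2:.2f}")

pd.concat(frames, ignore_index=True).to_csv(OUT / "blups.tsv", sep="\t", index=False)
print(f"wrote {OUT / 'blups.tsv'}")
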