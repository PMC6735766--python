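#!/usr/bin/env python
"""Simulate the two-transect common-garden study and write its files.

Emits VCF genotypes, GFF3 gene models, phenotype/climate/sample TSVs and the
ground-truth JSON under results/data/, then prints the study dimensions and
the planted causal architecture.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

from _common import DATA, DEMO_SIMULATION
from clinescan.simulate import SimulationConfig, simulate_study, write_study

cfg = SimulationConfig(**DEMO_SIMULATION)
study = simulate_study(cfg)
paths = write_study(study, DATA)

t = study.truth
print(f"wrote study to {DATA}")
print(f"  clones: {len(study.samples)} "
      f"(lat {sum(study.samples.transect == 'lat')}, "
      f"alt {sum(study.samples.transect == 'alt')})")
print(f"  SNPs: {study.variants.n_snps} in {len(study.genes)} genes + intergenic")
print(f"  phenotype records: {len(study.phenotypes)}")
print(f"  causal genes: lat {len(t.causal_genes['lat'])}, "
      f"alt {len(t.causal_genes['alt'])}, shared {len(t.shared_genes)}")
print("  files:", json.dumps({k: str(v) for k, v in paths.items()}, indent=2))
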