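"""Shared paths and loaders for the numbered analysis drivers.

Driver outputs live under results/; the simulated study written by
01_simulate_study.py is the input to every later step.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
DATA = RESULTS / "data"

# a moderate demo scale: full design structure at ~1/4 the SNP count so each
# driver runs in seconds; scripts/acceptance.py runs the full-scale studies
DEMO_SIMULATION = {
    "n_genes": 800,
    "snps_per_gene": 10.0,
    "n_intergenic_snps": 2000,
    "n_causal_genes_lat": 6,
    "n_causal_genes_alt": 6,
    "n_causal_shared": 3,
    "seed": 1,
}


def load_study():
    from clinescan.io_binning import read_genotypes, read_gff3_genes

    vt = read_genotypes(DATA / "genotypes.vcf")
    genes = read_gff3_genes(DATA / "genes.gff3")
    phenotypes = pd.read_csv(DATA / "phenotypes.tsv", sep="\t")
    climate = pd.read_csv(DATA / "climate.tsv", sep="\t")
    samples = pd.read_csv(DATA / "samples.tsv", sep="\t")
    return vt, genes, phenotypes, climate, samples


def out_dir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
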