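import numpy as np
import pandas as pd
import pytest

from clinescan.io_binning import VariantTable
from clinescan.simulate import SimulationConfig, simulate_study, write_study


SMALL_CONFIG = SimulationConfig(
    n_provenances_lat=12,
    n_provenances_alt=6,
    clones_per_provenance=6,
    clones_per_provenance_alt=12,
    n_genes=150,
    snps_per_gene=8.0,
    n_intergenic_snps=400,
    n_causal_genes_lat=6,
    n_causal_genes_alt=6,
    n_causal_shared=3,
    seed=11,
)


@pytest.fixture(scope="session")
def small_study():
    """A small but complete two-transect study shared across tests."""
    return simulate_study(SMALL_CONFIG)


@pytest.fixture(scope="session")
def small_study_files(small_study, tmp_path_factory):
    out = tmp_path_factory.mktemp("study")
    return write_study(small_study, out)


def make_variant_table(dosages, chrom=None, pos=None, snp_prefix="s"):
    """VariantTable from a plain dosage matrix (samples x SNPs)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    return VariantTable(
        snp_id=np.array([f"{snp_prefix}{j}" for j in range(m)], dtype=object),
        chrom=np.array(chrom if chrom is not None else ["chr01"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1), dtype=int),
        ref=np.array(["A"] * m, dtype=object),
        alt=np.array(["G"] * m, dtype=object),
        dosages=d,
        samples=[f"ind{i}" for i in range(n)],
    )


@pytest.fixture
def toy_vt():
    return make_variant_table
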