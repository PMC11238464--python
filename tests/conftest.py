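import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from egwas.genotype import GenotypeDataset
from egwas.grm import build_grm, stabilize
from egwas.simulate import SimConfig, simulate_genotypes

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_genotypes(dosages, chrom=None, pos=None, sample_ids=None) -> GenotypeDataset:
    """Small hand-built genotype dataset from a dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    snp_map = pd.DataFrame(
        {
            "chrom": chrom if chrom is not None else ["1"] * m,
            "snp_id": [f"s{j}" for j in range(m)],
            "pos": pos if pos is not None else np.arange(1, m + 1) * 1000,
            "a1": "A",
            "a2": "G",
        }
    )
    ids = sample_ids or [f"I{i}" for i in range(n)]
    return GenotypeDataset(sample_ids=ids, snp_map=snp_map, dosages=dosages)


@pytest.fixture(scope="session")
def geno_10k():
    """100 samples x 10,000 SNPs, used for GRM expectation and variance
    component recovery checks."""
    return simulate_genotypes(SimConfig(seed=7, n_snps=10_000))


@pytest.fixture(scope="session")
def grm_10k(geno_10k):
    return stabilize(build_grm(geno_10k))


@pytest.fixture()
def tiny_sim_config():
    """Fast simulator settings for structural tests."""
    return SimConfig(
        n_samples=30,
        n_snps=300,
        n_chromosomes=3,
        chrom_length_bp=5_000_000,
        n_genes=12,
        n_cis_eqtl=3,
        n_hotspots=1,
        hotspot_n_targets=5,
        batch_sizes=(16, 14),
        seed=5,
    )
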