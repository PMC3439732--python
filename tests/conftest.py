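import numpy as np
import pytest

from hnbgwas.dataset import CASE, CONTROL, GenotypeDataset
from hnbgwas.simulate import scenario_preset, simulate_dataset


def make_toy_dataset(dosage, labels, chrom=None, pos=None, snp_ids=None):
    """Small hand-built dataset; dosage rows are individuals."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    snp_ids = snp_ids or [f"s{j + 1}" for j in range(m)]
    return GenotypeDataset(
        sample_ids=[f"i{i + 1}" for i in range(n)],
        labels=np.asarray(labels),
        snp_ids=snp_ids,
        chrom=np.array(chrom if chrom is not None else ["1"] * m, dtype=object),
        pos=np.array(pos if pos is not None else np.arange(1, m + 1) * 100),
        allele1=np.array(["A"] * m, dtype=object),
        allele2=np.array(["G"] * m, dtype=object),
        counted_allele=np.array(["A"] * m, dtype=object),
        dosage=dosage,
    )


@pytest.fixture(scope="session")
def toy_factory():
    return make_toy_dataset


@pytest.fixture(scope="session")
def sim_small():
    """One small scenario-3 dataset reused across tests (100/100, 400 SNPs)."""
    sc = scenario_preset(3, seed=42, n_snps=400, n_blocks=12,
                         n_cases=100, n_controls=100)
    ds, truth = simulate_dataset(sc)
    return ds, truth


@pytest.fixture(scope="session")
def sim_full():
    """One full-scale scenario-3 dataset (300/300, 2000 SNPs)."""
    sc = scenario_preset(3, seed=7)
    ds, truth = simulate_dataset(sc)
    return ds, truth
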