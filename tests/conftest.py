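import numpy as np
import pandas as pd
import pytest

from stockload.genotype_io import MISSING, Genotypes


def make_genotypes(dosage, individual_ids=None, locus_ids=None, pos=None):
    """Build a Genotypes object from a plain dosage matrix."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    individual_ids = individual_ids or [f"ind{i}" for i in range(n)]
    locus_ids = locus_ids or [f"loc{j}" for j in range(m)]
    pos = np.asarray(pos if pos is not None else np.arange(1, m + 1))
    return Genotypes(
        individual_ids=individual_ids,
        snp_ids=[f"{l}_{p}" for l, p in zip(locus_ids, pos)],
        locus_ids=list(locus_ids),
        chrom=np.array(locus_ids, dtype=object),
        pos=pos,
        dosage=dosage,
        ref_allele=np.array(["A"] * m, dtype=object),
        alt_allele=np.array(["G"] * m, dtype=object),
    )


def two_pop_map(g, split):
    """Population map putting the first ``split`` individuals in pop A."""
    codes = ["A" if i < split else "B" for i in range(g.n_individuals)]
    return pd.Series(codes, index=g.individual_ids)


@pytest.fixture(scope="session")
def small_dataset():
    """One modest synthetic dataset shared across tests."""
    from stockload.synthetic_data import SimulationConfig, simulate_dataset
    return simulate_dataset(SimulationConfig(n_loci=150, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240601)
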