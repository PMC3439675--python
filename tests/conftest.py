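"""Shared fixtures: small handcrafted datasets and simulated GWAS panels."""

import numpy as np
import pytest

from bonb.gwas_data import CASE, CONTROL, MISSING, GenotypeDataset, SnpInfo
from bonb.ensemble import BonbParams, train
from bonb.synthetic import SimSpec, simulate, standard_fixture


def make_dataset(genotypes, labels, chromosomes=None, positions=None):
    """Build a GenotypeDataset from plain lists with auto-generated ids."""
    genotypes = np.asarray(genotypes, dtype=np.int8)
    n, p = genotypes.shape
    chromosomes = chromosomes or ["1"] * p
    positions = positions or [1 + 2_000_000 * j for j in range(p)]
    return GenotypeDataset(
        genotypes=genotypes,
        snps=[SnpInfo(f"snp{j}", chromosomes[j], positions[j]) for j in range(p)],
        labels=np.asarray(labels, dtype=np.int8),
        subject_ids=[f"s{i}" for i in range(n)],
    )


@pytest.fixture
def tiny_ds():
    """4 subjects x 3 SNPs with one missing genotype."""
    return make_dataset(
        [[0, 1, 2], [0, 0, 1], [1, MISSING, 2], [2, 2, 0]],
        [CASE, CASE, CONTROL, CONTROL],
    )


@pytest.fixture(scope="session")
def small_sim():
    """150 subjects, 6 LD blocks x 5 SNPs, one strongly causal block."""
    spec = SimSpec(
        n_cases=60,
        n_controls=90,
        n_blocks=6,
        block_size=5,
        within_block_r2=0.7,
        causal_blocks=((1, (0.9, 0.5, 0.1)),),
        maf_range=(0.2, 0.4),
        missing_rate=0.01,
        seed=42,
    )
    return simulate(spec)


@pytest.fixture(scope="session")
def std_fixture():
    """The canonical 1,000 x 500 dataset with 3 causal blocks."""
    return standard_fixture()


@pytest.fixture(scope="session")
def small_trained(small_sim):
    """B=20 ensemble trained on the small simulated panel."""
    ds, _ = small_sim
    return train(ds, BonbParams(B=20), seed=11)
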