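"""Shared fixtures: small deterministic cohorts, real and simulated."""

import numpy as np
import pytest

from logicgen.cohort_sim import SimConfig, simulate_cohort
from logicgen.haplotype_io import HaplotypeMatrix, VariantSite


def make_matrix(rows, positions=None, chrom="1"):
    """Hand matrix -> HaplotypeMatrix with 1 kb-spaced positions by default."""
    rows = np.asarray(rows, dtype=np.uint8)
    if positions is None:
        positions = [(j + 1) * 1000 for j in range(rows.shape[1])]
    sites = [VariantSite(chrom=chrom, pos=p) for p in positions]
    return HaplotypeMatrix(
        sites=sites, rows=rows, row_labels=[f"h{i}_0" for i in range(rows.shape[0])]
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def random_matrix():
    """20 x 30 unstructured binary matrix."""
    g = np.random.default_rng(7)
    return make_matrix(g.integers(0, 2, size=(20, 30)))


@pytest.fixture(scope="session")
def small_cohort():
    """60 haplotypes x 80 sites, two populations with LD blocks."""
    m, labels = simulate_cohort(
        SimConfig(n_samples=30, n_sites=80, n_pops=2, fst=0.15, seed=21)
    )
    return m


@pytest.fixture(scope="session")
def structured_cohort():
    """200 haplotypes x 300 sites, two populations; the generation-scale cohort."""
    m, labels = simulate_cohort(
        SimConfig(n_samples=100, n_sites=300, n_pops=2, fst=0.15, seed=1)
    )
    m.meta["pop_labels"] = labels
    return m
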