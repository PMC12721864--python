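"""Simulated haplotype cohorts for testing every other module without external data.

The simulator reproduces exactly the two structures the fidelity metrics
measure: population clusters in PCA space and windowed linkage
disequilibrium.  Population-specific allele frequencies follow the
Balding-Nichols construction (a Beta draw around an ancestral frequency
with variance set by FST); LD arises from founder-block copying — sites are
partitioned into blocks of geometric mean length, each population carries a
small pool of founder block-haplotypes, and every haplotype copies one
founder per block with a light mutation flip.  Within-block r-squared is
therefore high and between-block r-squared near zero.

Two planting helpers create the rare, identifying features the privacy
modules audit: a 4-site allele combination carried by exactly one row, and
a singleton variant site whose alternate allele one single row carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .haplotype_io import HaplotypeMatrix, VariantSite
from .privacy_metrics import count_pattern

__all__ = [
    "SimConfig",
    "PlantedQuadruplet",
    "simulate_cohort",
    "plant_unique_quadruplet",
    "plant_singleton_variant",
]


@dataclass
class SimConfig:
    """Study-condition parameters for the simulated cohort.

    Defaults emulate a small two-population cohort with visible PCA
    separation (FST 0.15) and block LD over ~10-site (10 kb) blocks, with
    ancestral minor allele frequencies between 0.05 and 0.5.
    """

    n_samples: int = 100  # diploid samples; the cohort has 2x this many rows
    n_sites: int = 300
    n_pops: int = 2
    fst: float = 0.15
    block_len: float = 10.0  # mean LD-block length in sites (1 site = 1 kb)
    maf_range: tuple[float, float] = (0.05, 0.5)
    seed: int = 0
    n_founders: int = 4  # founder block-haplotypes per population per block
    mutation_rate: float = 0.01  # per-allele copy-error probability

    def __post_init__(self) -> None:
        if min(self.n_samples, self.n_sites, self.n_pops, self.n_founders) < 1:
            raise ValueError("all counts must be positive")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must lie in [0, 1)")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must be within (0, 0.5]")
        if self.block_len < 1:
            raise ValueError("block_len must be >= 1")
        if not 0.0 <= self.mutation_rate < 0.5:
            raise ValueError("mutation_rate must lie in [0, 0.5)")


def _block_bounds(n_sites: int, mean_len: float, rng: np.random.Generator):
    bounds = []
    start = 0
    while start < n_sites:
        length = int(rng.geometric(1.0 / mean_len)) if mean_len > 1 else 1
        length = max(1, min(length, n_sites - start))
        bounds.append((start, start + length))
        start += length
    return bounds


def simulate_cohort(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[HaplotypeMatrix, np.ndarray]:
    """Simulate a cohort; returns the matrix and a per-row population label array."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n_rows = 2 * config.n_samples
    p0 = rng.uniform(*config.maf_range, size=config.n_sites)
    if config.fst > 0:
        shape = (1.0 - config.fst) / config.fst
        pop_freq = rng.beta(
            p0 * shape, (1.0 - p0) * shape, size=(config.n_pops, config.n_sites)
        )
        pop_freq = np.clip(pop_freq, 1e-6, 1 - 1e-6)
    else:
        pop_freq = np.tile(p0, (config.n_pops, 1))
    # contiguous population assignment, both haplotypes of a sample together
    sample_pop = np.minimum(
        (np.arange(config.n_samples) * config.n_pops) // config.n_samples,
        config.n_pops - 1,
    )
    labels = np.repeat(sample_pop, 2)
    rows = np.empty((n_rows, config.n_sites), dtype=np.uint8)
    blocks = _block_bounds(config.n_sites, config.block_len, rng)
    for lo, hi in blocks:
        # shared uniforms couple the populations: at fst=0 their founder
        # pools coincide exactly, so populations are exchangeable
        u = rng.random((config.n_founders, hi - lo))
        for k in range(config.n_pops):
            members = np.flatnonzero(labels == k)
            founders = (u < pop_freq[k, lo:hi]).astype(np.uint8)
            choice = rng.integers(config.n_founders, size=members.size)
            block = founders[choice]
            flips = rng.random(block.shape) < config.mutation_rate
            rows[members, lo:hi] = block ^ flips
    sites = [VariantSite(chrom="1", pos=(j + 1) * 1000) for j in range(config.n_sites)]
    row_labels = [
        f"pop{sample_pop[s]}_s{s}_{h}" for s in range(config.n_samples) for h in (0, 1)
    ]
    matrix = HaplotypeMatrix(
        sites=sites, rows=rows, row_labels=row_labels, meta={"simulated": True}
    )
    return matrix, labels


@dataclass(frozen=True)
class PlantedQuadruplet:
    """Record of a planted rare feature: carrier row, sites, alleles."""

    row: int
    sites: tuple[int, ...]
    alleles: tuple[int, ...]


def plant_unique_quadruplet(
    matrix: HaplotypeMatrix,
    rng: np.random.Generator,
    max_draws: int = 1000,
) -> tuple[HaplotypeMatrix, PlantedQuadruplet]:
    """Write a previously-absent 4-site pattern into exactly one random row.

    Returns a new matrix and the planted record; ``count_pattern`` on the
    result returns exactly 1 for the planted combination.
    """
    if matrix.n_sites < 4 or matrix.n_haplotypes < 2:
        raise ValueError("need >= 4 sites and >= 2 rows")
    for _ in range(max_draws):
        sites = tuple(
            int(s) for s in np.sort(rng.choice(matrix.n_sites, 4, replace=False))
        )
        alleles = tuple(int(a) for a in rng.integers(0, 2, size=4))
        if count_pattern(matrix, sites, alleles) == 0:
            row = int(rng.integers(matrix.n_haplotypes))
            new_rows = matrix.rows.copy()
            new_rows[row, list(sites)] = alleles
            planted = HaplotypeMatrix(
                sites=list(matrix.sites),
                rows=new_rows,
                row_labels=list(matrix.row_labels),
                meta=dict(matrix.meta),
            )
            assert count_pattern(planted, sites, alleles) == 1
            return planted, PlantedQuadruplet(row=row, sites=sites, alleles=alleles)
    raise RuntimeError(f"no absent quadruplet found within {max_draws} draws")


def plant_singleton_variant(
    matrix: HaplotypeMatrix, site: int, rng: np.random.Generator
) -> tuple[HaplotypeMatrix, PlantedQuadruplet]:
    """Make ``site`` a singleton variant: one random carrier, all other rows 0.

    Every pairwise pattern (1, *) anchored at the site is then uniquely
    supported by the carrier — the sharpest possible identifying feature for
    the reverse audit.
    """
    site = int(site)
    if not 0 <= site < matrix.n_sites:
        raise IndexError("site out of range")
    row = int(rng.integers(matrix.n_haplotypes))
    new_rows = matrix.rows.copy()
    new_rows[:, site] = 0
    new_rows[row, site] = 1
    planted = HaplotypeMatrix(
        sites=list(matrix.sites),
        rows=new_rows,
        row_labels=list(matrix.row_labels),
        meta=dict(matrix.meta),
    )
    return planted, PlantedQuadruplet(row=row, sites=(site,), alleles=(1,))
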