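"""Proxy privacy statistics.

Two complementary probes of how much a synthetic cohort reveals about the
real one:

* *Attribute inference*: split the real cohort into random halves, generate
  synthetic data from each, and compare each real haplotype's nearest-
  neighbour Hamming distance to the synthetic set built *with* it (in-data)
  versus *without* it (out-data).  The excess of the out-data median over
  the in-data median ("leakage") measures how much better an attacker could
  impute a target's alleles because the target was in the training half.

* *Quadruplet revelation*: sample 4-site allele combinations, label each
  *private* (carried by exactly one real haplotype) or *fictitious* (carried
  by none), and measure how often each class appears in synthetic output.
  Revealed private quadruplets are identifying; fictitious ones are
  hallucinations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .generator_core import GenomatorParams, generate
from .haplotype_io import HaplotypeMatrix

__all__ = [
    "Quadruplet",
    "RevelationReport",
    "AttributeInferenceReport",
    "count_pattern",
    "sample_labelled_quadruplets",
    "quadruplet_revelation",
    "nearest_hamming",
    "attribute_inference_experiment",
]


def count_pattern(matrix: HaplotypeMatrix, sites, alleles) -> int:
    """Number of rows carrying the given alleles at the given (distinct) sites."""
    sites = np.asarray(sites, dtype=np.intp)
    alleles = np.asarray(alleles, dtype=np.uint8)
    if sites.shape != alleles.shape:
        raise ValueError("sites and alleles must have equal length")
    if len(set(sites.tolist())) != sites.size:
        raise ValueError("sites must be distinct")
    if sites.size == 0:
        return matrix.n_haplotypes
    if sites.min() < 0 or sites.max() >= matrix.n_sites:
        raise IndexError("site index out of range")
    return int((matrix.rows[:, sites] == alleles[None, :]).all(axis=1).sum())


@dataclass(frozen=True)
class Quadruplet:
    """Four distinct sites, their alleles, and the label from the real cohort."""

    sites: tuple[int, int, int, int]
    alleles: tuple[int, int, int, int]
    label: str  # "private" (real_count == 1) or "fictitious" (real_count == 0)
    real_count: int


def sample_labelled_quadruplets(
    matrix: HaplotypeMatrix,
    quota_private: int,
    quota_fictitious: int,
    rng: np.random.Generator,
    max_draws: int | None = None,
) -> list[Quadruplet]:
    """Rejection-sample distinct quadruplets until both label quotas are met.

    Each draw picks 4 distinct sites uniformly and 4 alleles uniformly; the
    draw is kept only if its real-cohort count labels it private (1) or
    fictitious (0) and the relevant quota is open.  If ``max_draws`` (default
    ``200 * (quota_private + quota_fictitious)``) is exhausted first, the
    partial list is returned with a warning.
    """
    if matrix.n_sites < 4:
        raise ValueError("need at least 4 sites")
    if max_draws is None:
        max_draws = 200 * max(1, quota_private + quota_fictitious)
    seen: set[tuple] = set()
    out: list[Quadruplet] = []
    n_private = n_fictitious = 0
    draws = 0
    while (n_private < quota_private or n_fictitious < quota_fictitious) and draws < max_draws:
        draws += 1
        sites = tuple(int(s) for s in np.sort(rng.choice(matrix.n_sites, 4, replace=False)))
        alleles = tuple(int(a) for a in rng.integers(0, 2, size=4))
        key = (sites, alleles)
        if key in seen:
            continue
        seen.add(key)
        c = count_pattern(matrix, sites, alleles)
        if c == 1 and n_private < quota_private:
            out.append(Quadruplet(sites, alleles, "private", c))
            n_private += 1
        elif c == 0 and n_fictitious < quota_fictitious:
            out.append(Quadruplet(sites, alleles, "fictitious", c))
            n_fictitious += 1
    if n_private < quota_private or n_fictitious < quota_fictitious:
        warnings.warn(
            f"quadruplet quotas not met within {max_draws} draws "
            f"(private {n_private}/{quota_private}, "
            f"fictitious {n_fictitious}/{quota_fictitious})",
            stacklevel=2,
        )
    return out


@dataclass
class RevelationReport:
    """Per-label revelation of sampled quadruplets across synthetic datasets."""

    n_quadruplets: dict
    n_datasets: int
    #: fraction of quadruplets appearing in >= 1 synthetic dataset (headline)
    any_dataset_likelihood: dict
    #: mean over quadruplets of the fraction of datasets containing them
    mean_per_dataset_rate: dict


def quadruplet_revelation(
    quadruplets: list[Quadruplet],
    synthetic_datasets: list[HaplotypeMatrix],
) -> RevelationReport:
    """How often do labelled quadruplets occur in the synthetic datasets?"""
    if not synthetic_datasets:
        raise ValueError("need at least one synthetic dataset")
    n_sites = synthetic_datasets[0].n_sites
    for d in synthetic_datasets:
        if d.n_sites != n_sites:
            raise ValueError("synthetic datasets disagree on site count")
    labels = ("private", "fictitious")
    hits = {lab: [] for lab in labels}
    for q in quadruplets:
        if max(q.sites) >= n_sites:
            raise ValueError(
                f"quadruplet sites {q.sites} out of range for {n_sites} sites"
            )
        per_ds = [count_pattern(d, q.sites, q.alleles) >= 1 for d in synthetic_datasets]
        hits[q.label].append(per_ds)
    n_q = {lab: len(hits[lab]) for lab in labels}
    any_lik = {}
    mean_rate = {}
    for lab in labels:
        if n_q[lab] == 0:
            any_lik[lab] = float("nan")
            mean_rate[lab] = float("nan")
            continue
        arr = np.asarray(hits[lab], dtype=bool)
        any_lik[lab] = float(arr.any(axis=1).mean())
        mean_rate[lab] = float(arr.mean())
    return RevelationReport(
        n_quadruplets=n_q,
        n_datasets=len(synthetic_datasets),
        any_dataset_likelihood=any_lik,
        mean_per_dataset_rate=mean_rate,
    )


def nearest_hamming(queries: np.ndarray, pool: np.ndarray) -> np.ndarray:
    """Nearest-neighbour Hamming distance of each query row to the pool."""
    q = np.asarray(queries, dtype=np.int32)
    p = np.asarray(pool, dtype=np.int32)
    ones = q @ p.T
    d = q.sum(axis=1)[:, None] + p.sum(axis=1)[None, :] - 2 * ones
    return d.min(axis=1)


@dataclass
class AttributeInferenceReport:
    """Median in/out nearest-neighbour distances and their difference."""

    in_median: float
    out_median: float
    leakage: float  # out_median - in_median
    split_seed: int
    n_per_half: int
    in_distances: np.ndarray
    out_distances: np.ndarray


def attribute_inference_experiment(
    matrix: HaplotypeMatrix,
    params: GenomatorParams,
    n_synthetic_per_half: int = 120,
    rng: np.random.Generator | None = None,
    generator=None,
) -> AttributeInferenceReport:
    """Split-half attribute-inference probe.

    The cohort rows are split into two random equal halves; synthetic data is
    generated from each half; every real row's nearest-neighbour Hamming
    distance to its own half's synthetic set (in-data) and to the other
    half's (out-data) is computed and the two medians compared.

    ``generator(half_matrix, count, rng) -> HaplotypeMatrix`` is injectable
    so the probe can score any generation method; the default runs this
    package's generator with ``params``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = matrix.n_haplotypes
    half = n // 2
    if generator is None:
        if half < params.cluster_size:
            raise ValueError(
                f"half size {half} is smaller than cluster_size {params.cluster_size}"
            )
        def generator(m, count, g):
            return generate(m, params, count, g)[0]
    perm = rng.permutation(n)
    idx_a, idx_b = perm[:half], perm[half : 2 * half]
    half_a = matrix.subset_rows(idx_a)
    half_b = matrix.subset_rows(idx_b)
    synth_a = generator(half_a, n_synthetic_per_half, rng)
    synth_b = generator(half_b, n_synthetic_per_half, rng)
    in_d = np.concatenate(
        (nearest_hamming(half_a.rows, synth_a.rows),
         nearest_hamming(half_b.rows, synth_b.rows))
    )
    out_d = np.concatenate(
        (nearest_hamming(half_a.rows, synth_b.rows),
         nearest_hamming(half_b.rows, synth_a.rows))
    )
    in_med = float(np.median(in_d))
    out_med = float(np.median(out_d))
    return AttributeInferenceReport(
        in_median=in_med,
        out_median=out_med,
        leakage=out_med - in_med,
        split_seed=params.seed,
        n_per_half=n_synthetic_per_half,
        in_distances=in_d,
        out_distances=out_d,
    )
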