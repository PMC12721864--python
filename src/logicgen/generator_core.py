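"""Synthetic haplotype generation by pairwise-pattern logic solving.

One synthetic haplotype is produced per SAT solve.  The cohort is first
organised into overlapping clusters (one per haplotype: the seed plus its
``N - 1`` Hamming-nearest neighbours).  For a randomly chosen cluster a CNF
over one Boolean variable per site (true = alternate allele) is built: for
every considered site pair, each of the four joint allele patterns whose
observed frequency in the cluster is at or below a randomized integer
threshold ``z`` is forbidden by a 2-literal clause.  ``z`` is drawn per pair
as ``floor(Uniform[0, alpha + 1))``; at ``alpha = 0`` exactly the unobserved
patterns are forbidden, so every cluster member remains a model and the
problem is always satisfiable.  The exclusion probability ``L`` drops each
site pair independently with probability ``L`` before constraints are built,
trading constraint density (accuracy) for solver freedom (privacy and
speed).

The tuning triple (cluster size ``N``, exclusion probability ``L``, privacy
parameter ``alpha``) defaults to ``N=150, L=0.99, alpha=0.5``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._sat import TwoSat
from .haplotype_io import HaplotypeMatrix, VariantSite

__all__ = [
    "GenomatorParams",
    "Cluster",
    "PatternAudit",
    "ConstraintProblem",
    "GenerationRecord",
    "GenerationError",
    "draw_z",
    "build_clusters",
    "sample_pair_universe",
    "pattern_frequencies",
    "build_constraints",
    "solve_constraints",
    "clauses_satisfied",
    "generate",
]

#: joint allele patterns per site pair, in lexicographic order
PATTERNS = ((0, 0), (0, 1), (1, 0), (1, 1))


class GenerationError(RuntimeError):
    """Persistent unsatisfiability that survived retries and the alpha fallback."""


@dataclass
class GenomatorParams:
    """Tuning parameters for generation.

    Attributes
    ----------
    cluster_size
        ``N``: haplotypes per cluster; larger clusters admit more patterns
        and therefore less constrained output.
    exclusion_prob
        ``L``: each site pair is *ignored* with this probability when
        building constraints.
    privacy_alpha
        ``alpha``: the randomized suppression threshold ``z`` is drawn as
        ``floor(Uniform[0, alpha + 1))`` per pair; patterns observed at
        frequency <= z are forbidden, attenuating rare identifying
        combinations.
    seed
        Run seed; fixed seed gives bit-identical output.
    max_retries
        Solver retries (fresh pair universe and z draws) before ``alpha``
        is halved.
    freeze_pair_universe
        If true, one pair universe is sampled for the whole run instead of
        per synthetic haplotype.
    polarity
        Solver decision polarity for free choices: ``"frequency"`` tries the
        alternate allele with its cluster frequency (realistic marginals),
        ``"uniform"`` with probability 1/2 (maximal solver diversity).
    """

    cluster_size: int = 150
    exclusion_prob: float = 0.99
    privacy_alpha: float = 0.5
    seed: int = 0
    max_retries: int = 10
    freeze_pair_universe: bool = False
    polarity: str = "frequency"

    def __post_init__(self) -> None:
        if self.cluster_size < 1:
            raise ValueError("cluster_size must be a positive integer")
        if not 0.0 <= self.exclusion_prob <= 1.0:
            raise ValueError("exclusion_prob must lie in [0, 1]")
        if self.privacy_alpha < 0:
            raise ValueError("privacy_alpha must be >= 0")
        if self.max_retries < 1:
            raise ValueError("max_retries must be positive")
        if self.polarity not in ("frequency", "uniform"):
            raise ValueError('polarity must be "frequency" or "uniform"')


@dataclass(frozen=True)
class Cluster:
    """A seed haplotype and its ``N`` member rows (seed first, then by distance)."""

    seed_row: int
    members: tuple[int, ...]


@dataclass(frozen=True)
class PatternAudit:
    """Provenance of one forbidden pattern: pair, pattern, its frequency, the z draw."""

    pair: tuple[int, int]
    pattern: tuple[int, int]
    observed_frequency: int
    drawn_z: int


@dataclass
class ConstraintProblem:
    """CNF over one Boolean variable per site (true = alternate allele).

    ``polarity_bias`` carries the cluster's per-site alternate-allele
    frequencies; the solver uses them as decision-polarity probabilities so
    that free choices follow the cluster's marginal allele distribution.
    """

    n_vars: int
    clauses: np.ndarray  # (n_clauses, 2) DIMACS literals
    audit: list[PatternAudit] = field(default_factory=list)
    polarity_bias: np.ndarray | None = None


@dataclass(frozen=True)
class GenerationRecord:
    """Per-haplotype provenance."""

    index: int
    cluster_seed_row: int
    retries: int
    effective_alpha: float


def draw_z(privacy_alpha: float, rng: np.random.Generator) -> int:
    """One randomized suppression threshold: ``floor(Uniform[0, alpha + 1))``.

    For ``alpha = 0.5`` this is 1 with probability 1/3 and 0 otherwise; for
    integer ``alpha`` it is uniform on ``{0, ..., alpha}``.
    """
    if privacy_alpha < 0:
        raise ValueError("privacy_alpha must be >= 0")
    return int(rng.uniform(0.0, privacy_alpha + 1.0))


def build_clusters(matrix: HaplotypeMatrix, cluster_size: int) -> list[Cluster]:
    """One overlapping cluster per cohort haplotype.

    Each cluster is its seed row plus the ``cluster_size - 1`` nearest rows
    by Hamming distance, ties broken towards the lower row index.
    Deterministic given the matrix.
    """
    n = matrix.n_haplotypes
    if cluster_size > n:
        raise ValueError(
            f"cluster_size {cluster_size} exceeds cohort size {n}"
        )
    x = matrix.rows.astype(np.int32)
    # pairwise Hamming via mismatch counts: d = x(1-x)' + (1-x)x'
    ones = x @ x.T
    row_sums = x.sum(axis=1)
    dist = row_sums[:, None] + row_sums[None, :] - 2 * ones
    clusters = []
    idx = np.arange(n)
    for s in range(n):
        d = dist[s].copy()
        d[s] = -1  # the seed always comes first
        order = np.lexsort((idx, d))
        clusters.append(Cluster(seed_row=s, members=tuple(int(i) for i in order[:cluster_size])))
    return clusters


def sample_pair_universe(
    n_sites: int, exclusion_prob: float, rng: np.random.Generator
) -> np.ndarray:
    """The site pairs considered for constraints, as an ``(k, 2)`` array ``i < j``.

    Each of the ``C(n_sites, 2)`` unordered pairs is included independently
    with probability ``1 - exclusion_prob``.
    """
    if n_sites < 2:
        raise ValueError("need at least 2 sites")
    if not 0.0 <= exclusion_prob <= 1.0:
        raise ValueError("exclusion_prob must lie in [0, 1]")
    iu, ju = np.triu_indices(n_sites, k=1)
    keep = rng.random(iu.shape[0]) < 1.0 - exclusion_prob
    return np.column_stack((iu[keep], ju[keep])).astype(np.int64)


def pattern_frequencies(matrix: HaplotypeMatrix, members, pair) -> np.ndarray:
    """Counts of the four joint patterns (00, 01, 10, 11) over ``members`` at ``pair``."""
    members = np.asarray(members, dtype=np.intp)
    i, j = int(pair[0]), int(pair[1])
    code = 2 * matrix.rows[members, i].astype(np.intp) + matrix.rows[members, j]
    return np.bincount(code, minlength=4)


def build_constraints(
    matrix: HaplotypeMatrix,
    cluster: Cluster,
    pairs: np.ndarray,
    privacy_alpha: float,
    rng: np.random.Generator,
    collect_audit: bool = True,
) -> ConstraintProblem:
    """Forbid, per considered pair, every pattern with cluster frequency <= z.

    ``z`` is drawn independently per pair.  If all four patterns of a pair
    would be forbidden, the highest-frequency pattern (ties: lexicographically
    smallest) is left allowed so no pair is outright contradictory.
    """
    n_sites = matrix.n_sites
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    if pairs.shape[0] == 0:
        warnings.warn("empty pair universe: unconstrained problem", stacklevel=2)
        bias = matrix.rows[np.asarray(cluster.members, dtype=np.intp)].mean(axis=0)
        return ConstraintProblem(
            n_vars=n_sites,
            clauses=np.empty((0, 2), dtype=np.int64),
            polarity_bias=bias,
        )
    if pairs.max() >= n_sites:
        raise ValueError("pair index out of range")
    x = matrix.rows[np.asarray(cluster.members, dtype=np.intp)]
    a = x[:, pairs[:, 0]].astype(np.int64)
    b = x[:, pairs[:, 1]].astype(np.int64)
    c11 = (a & b).sum(axis=0)
    c10 = (a & (1 - b)).sum(axis=0)
    c01 = ((1 - a) & b).sum(axis=0)
    c00 = x.shape[0] - c11 - c10 - c01
    counts = np.stack((c00, c01, c10, c11), axis=1)  # (P, 4), pattern = 2a+b

    z = np.floor(rng.uniform(0.0, privacy_alpha + 1.0, size=pairs.shape[0])).astype(np.int64)
    forbid = counts <= z[:, None]
    all_four = forbid.all(axis=1)
    if all_four.any():
        keep = counts[all_four].argmax(axis=1)  # first max = lexicographically smallest
        forbid[np.flatnonzero(all_four), keep] = False

    pi, pp = np.nonzero(forbid)
    site_i = pairs[pi, 0]
    site_j = pairs[pi, 1]
    allele_i = pp >> 1
    allele_j = pp & 1
    # forbid (x_i == a, x_j == b)  ==>  clause (not[x_i == a] OR not[x_j == b])
    lit_i = np.where(allele_i == 1, -(site_i + 1), site_i + 1)
    lit_j = np.where(allele_j == 1, -(site_j + 1), site_j + 1)
    clauses = np.column_stack((lit_i, lit_j))
    audit: list[PatternAudit] = []
    if collect_audit:
        audit = [
            PatternAudit(
                pair=(int(site_i[t]), int(site_j[t])),
                pattern=(int(allele_i[t]), int(allele_j[t])),
                observed_frequency=int(counts[pi[t], pp[t]]),
                drawn_z=int(z[pi[t]]),
            )
            for t in range(pi.shape[0])
        ]
    return ConstraintProblem(
        n_vars=n_sites, clauses=clauses, audit=audit,
        polarity_bias=x.mean(axis=0),
    )


def clauses_satisfied(problem: ConstraintProblem, assignment: np.ndarray) -> bool:
    """Independent clause-by-clause check of a 0/1 assignment."""
    assignment = np.asarray(assignment, dtype=np.uint8)
    if problem.clauses.shape[0] == 0:
        return True
    lit = problem.clauses
    truth = assignment[np.abs(lit) - 1] == (lit > 0)
    return bool(truth.any(axis=1).all())


def solve_constraints(problem: ConstraintProblem, rng: np.random.Generator):
    """A randomized model of the CNF as a 0/1 site vector, or None if unsatisfiable.

    The returned assignment is re-verified clause by clause before return.
    """
    solver = TwoSat(problem.n_vars)
    solver.add_clauses(problem.clauses)
    model = solver.solve(rng, polarity_bias=problem.polarity_bias)
    if model is None:
        return None
    if not clauses_satisfied(problem, model):  # pragma: no cover - solver invariant
        raise AssertionError("solver returned a non-model")
    return model


def generate(
    matrix: HaplotypeMatrix,
    params: GenomatorParams,
    count: int,
    rng: np.random.Generator | None = None,
) -> tuple[HaplotypeMatrix, list[GenerationRecord]]:
    """Generate ``count`` synthetic haplotypes with a provenance log.

    For each output a cluster is chosen uniformly at random, a fresh pair
    universe is sampled, constraints are built and solved.  Unsatisfiable
    problems (possible only for ``alpha > 0``) are retried with fresh
    randomness; after ``max_retries`` failures ``alpha`` is halved (reaching
    0 within a few steps, where satisfiability is guaranteed).
    """
    if matrix.n_haplotypes < params.cluster_size:
        raise ValueError(
            f"cohort has {matrix.n_haplotypes} haplotypes, fewer than "
            f"cluster_size {params.cluster_size}"
        )
    if rng is None:
        rng = np.random.default_rng(params.seed)
    clusters = build_clusters(matrix, params.cluster_size)
    frozen = (
        sample_pair_universe(matrix.n_sites, params.exclusion_prob, rng)
        if params.freeze_pair_universe
        else None
    )
    out_rows = np.empty((count, matrix.n_sites), dtype=np.uint8)
    log: list[GenerationRecord] = []
    for k in range(count):
        cluster = clusters[int(rng.integers(len(clusters)))]
        alpha_eff = params.privacy_alpha
        retries = 0
        while True:
            pairs = frozen if frozen is not None else sample_pair_universe(
                matrix.n_sites, params.exclusion_prob, rng
            )
            problem = build_constraints(
                matrix, cluster, pairs, alpha_eff, rng, collect_audit=False
            )
            if params.polarity == "uniform":
                problem.polarity_bias = None
            model = solve_constraints(problem, rng)
            if model is not None:
                break
            retries += 1
            if retries % params.max_retries == 0:
                if alpha_eff == 0.0:  # pragma: no cover - alpha=0 is satisfiable
                    raise GenerationError(
                        f"unsatisfiable at alpha=0 for haplotype {k}"
                    )
                alpha_eff = alpha_eff / 2.0 if alpha_eff > 1e-3 else 0.0
        out_rows[k] = model
        log.append(
            GenerationRecord(
                index=k,
                cluster_seed_row=cluster.seed_row,
                retries=retries,
                effective_alpha=alpha_eff,
            )
        )
    synth = HaplotypeMatrix(
        sites=[VariantSite(s.chrom, s.pos, s.id, s.ref, s.alt) for s in matrix.sites],
        rows=out_rows,
        row_labels=[f"synth{k}_0" for k in range(count)],
        meta={"generator": "logicgen", "count": count},
    )
    return synth, log
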