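"""Reverse auditing: which input subsets could have produced a synthetic haplotype?

Generation with exclusion probability ``L = 0`` has one certain logical
consequence: every pairwise allele pattern of the output had observed
frequency >= 1 in the source cluster (frequency-0 patterns are forbidden for
every ``z >= 0``).  The reverse problem therefore asks, for a candidate
subset ``S`` of ``M`` cohort rows: does every considered site pair have at
least one member of ``S`` exhibiting the target's pattern there?  Encoded
over one selection variable per cohort row this is a CNF of positive
"support" clauses plus an exactly-``M`` cardinality constraint.

Enumerating many distinct feasible subsets and intersecting them estimates
the *backbone* — rows present in every feasible subset.  A non-empty
intersection means some individual's membership in the input is logically
deducible from the synthetic haplotype: they are *exposed*.  The audit is
defined for the ``L = 0`` regime only; with ``L > 0`` the generation
consequence is probabilistic and no sound constraint exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from ._sat import SelectionSolver
from .generator_core import build_constraints, solve_constraints, Cluster
from .haplotype_io import HaplotypeMatrix

__all__ = [
    "InfeasibleTargetError",
    "ReconstructionProblem",
    "Reconstructions",
    "ExposureReport",
    "all_site_pairs",
    "build_reconstruction_problem",
    "cluster_supports_target",
    "enumerate_reconstructions",
    "exposed_members",
    "certify_exposure",
    "exposure_risk_experiment",
]


class InfeasibleTargetError(ValueError):
    """Some pattern of the target is supported by no cohort row at all."""

    def __init__(self, pair: tuple[int, int], pattern: tuple[int, int]):
        self.pair = pair
        self.pattern = pattern
        super().__init__(
            f"pattern {pattern} at site pair {pair} is carried by no cohort row"
        )


def all_site_pairs(n_sites: int) -> np.ndarray:
    """All unordered site pairs, the ``L = 0`` pair universe."""
    iu, ju = np.triu_indices(n_sites, k=1)
    return np.column_stack((iu, ju)).astype(np.int64)


@dataclass
class ReconstructionProblem:
    """Selection CNF: support clauses over cohort rows + exactly-M cardinality."""

    cohort: HaplotypeMatrix
    target: np.ndarray
    subset_size: int
    pairs: np.ndarray
    support: dict  # (i, j) -> np.ndarray of supporting row indices
    clauses: list[tuple[int, ...]] = field(default_factory=list)  # unique, 1-based


def _support_matrix(cohort: HaplotypeMatrix, target: np.ndarray, pairs: np.ndarray):
    """Boolean (n_rows, n_pairs): row matches target's pattern at each pair."""
    t = np.asarray(target, dtype=np.uint8)
    a = cohort.rows[:, pairs[:, 0]] == t[pairs[:, 0]][None, :]
    b = cohort.rows[:, pairs[:, 1]] == t[pairs[:, 1]][None, :]
    return a & b


def build_reconstruction_problem(
    cohort: HaplotypeMatrix,
    target,
    subset_size: int,
    pairs: np.ndarray | None = None,
) -> ReconstructionProblem:
    """Encode "which M-row subsets could have produced ``target`` (L = 0)?".

    Raises :class:`InfeasibleTargetError` naming the first offending pair if
    some pattern of the target is carried by no cohort row.
    """
    target = np.asarray(target, dtype=np.uint8)
    if target.shape != (cohort.n_sites,):
        raise ValueError(
            f"target length {target.shape} != cohort site count {cohort.n_sites}"
        )
    if not 1 <= subset_size <= cohort.n_haplotypes:
        raise ValueError(
            f"subset_size {subset_size} outside 1..{cohort.n_haplotypes}"
        )
    if pairs is None:
        pairs = all_site_pairs(cohort.n_sites)
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    match = _support_matrix(cohort, target, pairs)
    empty = np.flatnonzero(~match.any(axis=0))
    if empty.size:
        i, j = (int(v) for v in pairs[empty[0]])
        raise InfeasibleTargetError((i, j), (int(target[i]), int(target[j])))
    support: dict[tuple[int, int], np.ndarray] = {}
    unique: dict[frozenset, tuple[int, ...]] = {}
    for p in range(pairs.shape[0]):
        rows = np.flatnonzero(match[:, p])
        key = (int(pairs[p, 0]), int(pairs[p, 1]))
        support[key] = rows
        fs = frozenset(int(r) for r in rows)
        if fs not in unique:
            unique[fs] = tuple(int(r) + 1 for r in rows)
    return ReconstructionProblem(
        cohort=cohort,
        target=target,
        subset_size=subset_size,
        pairs=pairs,
        support=support,
        clauses=list(unique.values()),
    )


def cluster_supports_target(problem: ReconstructionProblem, members) -> bool:
    """Direct check that a member set satisfies every support clause."""
    members = set(int(m) for m in members)
    return all(
        members.intersection(int(r) for r in rows) for rows in problem.support.values()
    )


@dataclass
class Reconstructions:
    """Distinct feasible subsets found by enumeration."""

    subsets: list[frozenset]
    exhausted: bool  # True when the whole solution space was enumerated

    def __len__(self) -> int:
        return len(self.subsets)

    def __iter__(self):
        return iter(self.subsets)


def enumerate_reconstructions(
    problem: ReconstructionProblem,
    count: int = 500,
    rng: np.random.Generator | None = None,
) -> Reconstructions:
    """Up to ``count`` distinct feasible subsets, diversified by randomized search.

    Distinctness is enforced with a blocking clause per found subset.  If the
    solution space runs out first, everything found is returned with
    ``exhausted=True``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    solver = SelectionSolver(
        n_vars=problem.cohort.n_haplotypes,
        clauses=problem.clauses,
        exactly=problem.subset_size,
    )
    found: list[frozenset] = []
    exhausted = False
    for _ in range(count):
        model = solver.solve(rng)
        if model is None:
            exhausted = True
            break
        subset = frozenset(v - 1 for v in model)
        found.append(subset)
        solver.add_clause([-v for v in model])
    return Reconstructions(subsets=found, exhausted=exhausted)


def exposed_members(reconstructions) -> frozenset:
    """Rows present in *every* reconstructed subset (the sampled backbone)."""
    subsets = list(reconstructions)
    if not subsets:
        raise ValueError("exposure is undefined for an empty reconstruction list")
    out = frozenset(subsets[0])
    for s in subsets[1:]:
        out &= frozenset(s)
        if not out:
            break
    return out


def certify_exposure(problem: ReconstructionProblem, member: int) -> bool:
    """Exact backbone test: is ``member`` in every feasible subset?

    True iff the problem with that row's selection variable forced false is
    unsatisfiable.
    """
    solver = SelectionSolver(
        n_vars=problem.cohort.n_haplotypes,
        clauses=problem.clauses,
        exactly=problem.subset_size,
    )
    model = solver.solve(np.random.default_rng(0), assumptions=[-(int(member) + 1)])
    return model is None


@dataclass
class ExposureReport:
    """Result of the iterated exposure-risk experiment."""

    n_snps: int
    subset_size: int
    n_reconstructions: int
    iterations: int
    failed_iterations: int
    exposed_sets: list[frozenset]
    exposed_flags: list[bool]
    risk: float
    ci_level: float
    ci_bounds: tuple[float, float]


def exposure_risk_experiment(
    cohort: HaplotypeMatrix,
    n_snps: int,
    subset_size: int,
    privacy_alpha: float,
    iterations: int,
    n_reconstructions: int = 500,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.90,
    max_solve_retries: int = 20,
) -> ExposureReport:
    """Estimate the probability that a synthetic haplotype logically exposes someone.

    Per iteration: ``n_snps`` sites and ``subset_size`` rows are sampled from
    the cohort; one synthetic haplotype is generated from exactly that row
    subset (cluster = the sampled rows, ``L = 0``, the given ``alpha``); the
    reconstruction problem over the same sites is built against the whole
    cohort and ``n_reconstructions`` distinct subsets are enumerated.  The
    iteration scores 1 if their intersection is non-empty.  Risk is the mean
    score with a Clopper-Pearson binomial interval at ``ci_level``.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if n_snps > cohort.n_sites:
        raise ValueError("n_snps exceeds the cohort site count")
    if subset_size > cohort.n_haplotypes:
        raise ValueError("subset_size exceeds the cohort row count")
    exposed_sets: list[frozenset] = []
    flags: list[bool] = []
    failed = 0
    for _ in range(iterations):
        sites = np.sort(rng.choice(cohort.n_sites, size=n_snps, replace=False))
        rows = rng.choice(cohort.n_haplotypes, size=subset_size, replace=False)
        sub = cohort.subset_sites(sites)
        cluster = Cluster(seed_row=int(rows[0]), members=tuple(int(r) for r in rows))
        pairs = all_site_pairs(n_snps)
        alpha_eff = privacy_alpha
        model = None
        tries = 0
        while model is None:
            problem = build_constraints(sub, cluster, pairs, alpha_eff, rng,
                                        collect_audit=False)
            model = solve_constraints(problem, rng)
            if model is None:
                tries += 1
                if tries % max_solve_retries == 0:
                    alpha_eff = alpha_eff / 2.0 if alpha_eff > 1e-3 else 0.0
        try:
            rec_problem = build_reconstruction_problem(sub, model, subset_size, pairs)
        except InfeasibleTargetError:
            # cannot happen when auditing against a pool containing the
            # cluster rows, but recorded rather than crashed if it does
            failed += 1
            continue
        recs = enumerate_reconstructions(rec_problem, n_reconstructions, rng)
        exposed = exposed_members(recs) if len(recs) else frozenset()
        exposed_sets.append(exposed)
        flags.append(bool(exposed))
    n_ok = len(flags)
    risk = float(np.mean(flags)) if n_ok else float("nan")
    if n_ok:
        lo, hi = proportion_confint(
            int(np.sum(flags)), n_ok, alpha=1.0 - ci_level, method="beta"
        )
        ci = (float(lo), float(hi))
    else:
        ci = (float("nan"), float("nan"))
    return ExposureReport(
        n_snps=n_snps,
        subset_size=subset_size,
        n_reconstructions=n_reconstructions,
        iterations=iterations,
        failed_iterations=failed,
        exposed_sets=exposed_sets,
        exposed_flags=flags,
        risk=risk,
        ci_level=ci_level,
        ci_bounds=ci,
    )
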