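"""Cohort fidelity statistics.

Three views of how well a synthetic cohort reproduces the real one:

* population structure — PCA fitted on the real haplotypes only, both
  cohorts projected, and the two projected clouds compared by the sliced
  Wasserstein distance (mean of 1-D optimal-transport distances over random
  unit directions);
* raw-data displacement — the same sliced distance over all site
  dimensions, reported as a percentage of the maximal possible displacement
  (the all-reference vs all-alternate clouds under the same directions);
* linkage disequilibrium — pairwise Rogers-Huff r-squared (on phased
  haplotypes this is the squared Pearson correlation of allele indicators),
  compared between cohorts as the mean squared error over SNP pairs within
  base-pair windows, with bootstrap confidence bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import wasserstein_distance
from sklearn.decomposition import PCA

from .haplotype_io import HaplotypeMatrix

__all__ = [
    "PCAReport",
    "LDReport",
    "pca_fit_project",
    "pca_wasserstein",
    "sliced_wasserstein",
    "raw_wasserstein_percent",
    "ld_r2_pairs",
    "ld_square_error",
]

DEFAULT_WINDOW_GRID = (50_000, 100_000, 150_000, 200_000, 250_000)


@dataclass
class PCAReport:
    components: np.ndarray  # (2, n_sites) loadings fit on the real cohort
    explained_variance: np.ndarray
    real_proj: np.ndarray
    synth_proj: np.ndarray
    score: float | None = None  # sliced Wasserstein between projected clouds
    n_projections: int | None = None
    seed: int | None = None


def pca_fit_project(
    real: HaplotypeMatrix,
    synthetic: HaplotypeMatrix,
    n_components: int = 2,
    fit_on: str = "real",
) -> PCAReport:
    """Fit PCA (default: on the real cohort only) and project both cohorts.

    ``fit_on="pooled"`` fits on the stacked cohorts instead, for sensitivity
    checks.
    """
    if real.n_sites != synthetic.n_sites:
        raise ValueError(
            f"site counts differ: real {real.n_sites}, synthetic {synthetic.n_sites}"
        )
    if fit_on not in ("real", "pooled"):
        raise ValueError(f"unknown fit_on policy {fit_on!r}")
    x_real = real.rows.astype(np.float64)
    x_synth = synthetic.rows.astype(np.float64)
    fit_data = x_real if fit_on == "real" else np.vstack((x_real, x_synth))
    pca = PCA(n_components=n_components)
    pca.fit(fit_data)
    return PCAReport(
        components=pca.components_,
        explained_variance=pca.explained_variance_,
        real_proj=pca.transform(x_real),
        synth_proj=pca.transform(x_synth),
    )


def sliced_wasserstein(
    a: np.ndarray,
    b: np.ndarray,
    n_projections: int = 100,
    rng: np.random.Generator | None = None,
    directions: np.ndarray | None = None,
) -> float:
    """Mean 1-D Wasserstein distance over random unit projection directions.

    Symmetric in its arguments and zero when the clouds coincide as
    multisets.  ``directions`` (rows normalised internally) overrides the
    random draw, e.g. for axis-aligned or single-direction checks.
    """
    a = np.atleast_2d(np.asarray(a, dtype=np.float64))
    b = np.atleast_2d(np.asarray(b, dtype=np.float64))
    if a.size == 0 or b.size == 0:
        raise ValueError("point clouds must be non-empty")
    if a.shape[1] != b.shape[1]:
        raise ValueError("point clouds must share dimensionality")
    if directions is None:
        if rng is None:
            rng = np.random.default_rng(0)
        directions = rng.normal(size=(n_projections, a.shape[1]))
    directions = np.atleast_2d(np.asarray(directions, dtype=np.float64))
    norms = np.linalg.norm(directions, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("zero-length projection direction")
    directions = directions / norms
    pa = a @ directions.T
    pb = b @ directions.T
    dists = [
        wasserstein_distance(pa[:, k], pb[:, k]) for k in range(directions.shape[0])
    ]
    return float(np.mean(dists))


def pca_wasserstein(
    real: HaplotypeMatrix,
    synthetic: HaplotypeMatrix,
    n_projections: int = 100,
    seed: int = 0,
    fit_on: str = "real",
) -> PCAReport:
    """Population-structure score: sliced Wasserstein on the 2-D PCA projections."""
    report = pca_fit_project(real, synthetic, n_components=2, fit_on=fit_on)
    rng = np.random.default_rng(seed)
    report.score = sliced_wasserstein(
        report.real_proj, report.synth_proj, n_projections=n_projections, rng=rng
    )
    report.n_projections = n_projections
    report.seed = seed
    return report


def raw_wasserstein_percent(
    real: HaplotypeMatrix,
    synthetic: HaplotypeMatrix,
    n_projections: int = 100,
    rng: np.random.Generator | None = None,
) -> float:
    """Sliced Wasserstein over all site dimensions, as % of maximal displacement.

    The yardstick is the sliced distance between the all-reference and
    all-alternate clouds under the same directions, so identical cohorts
    score 0% and the bitwise complement of a constant cohort scores 100%.
    """
    if real.n_sites != synthetic.n_sites:
        raise ValueError(
            f"site counts differ: real {real.n_sites}, synthetic {synthetic.n_sites}"
        )
    if rng is None:
        rng = np.random.default_rng(0)
    d = real.n_sites
    directions = rng.normal(size=(n_projections, d))
    num = sliced_wasserstein(real.rows, synthetic.rows, directions=directions)
    # max displacement: every site flips 0 -> 1, i.e. |sum(theta)| per direction
    unit = directions / np.linalg.norm(directions, axis=1, keepdims=True)
    den = float(np.mean(np.abs(unit.sum(axis=1))))
    return 100.0 * num / den


def _r2_matrix(rows: np.ndarray) -> np.ndarray:
    """Squared correlation of allele indicators; NaN where a site is monomorphic."""
    x = rows.astype(np.float64)
    xc = x - x.mean(axis=0)
    sd = x.std(axis=0)
    denom = np.outer(sd, sd) * x.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xc.T @ xc) / denom
    r2 = r * r
    mono = sd == 0
    r2[mono, :] = np.nan
    r2[:, mono] = np.nan
    return r2


def ld_r2_pairs(matrix: HaplotypeMatrix, max_window_bp: int) -> pd.DataFrame:
    """Rogers-Huff r-squared for same-chromosome site pairs within a window.

    Columns: ``site_i``, ``site_j``, ``dist_bp``, ``r2`` (NaN for pairs
    involving a monomorphic site).  Positions must be sorted (they are by
    the container invariant).
    """
    pos = matrix.positions
    chroms = matrix.chroms
    r2 = _r2_matrix(matrix.rows)
    iu, ju = np.triu_indices(matrix.n_sites, k=1)
    same = chroms[iu] == chroms[ju]
    dist = pos[ju] - pos[iu]
    if (dist[same] < 0).any():
        raise ValueError("positions are not sorted")
    keep = same & (dist <= max_window_bp)
    return pd.DataFrame(
        {
            "site_i": iu[keep],
            "site_j": ju[keep],
            "dist_bp": dist[keep],
            "r2": r2[iu[keep], ju[keep]],
        }
    )


@dataclass
class LDReport:
    """Windowed LD square error with bootstrap confidence bands."""

    table: pd.DataFrame  # window_bp, n_pairs, mean_sq_error, ci_low, ci_high
    n_boot: int
    ci_level: float


def ld_square_error(
    real: HaplotypeMatrix,
    synthetic: HaplotypeMatrix,
    window_grid=DEFAULT_WINDOW_GRID,
    n_boot: int = 1000,
    rng: np.random.Generator | None = None,
    ci_level: float = 0.95,
) -> LDReport:
    """Mean squared difference of pairwise r-squared, per base-pair window.

    Pairs with undefined r-squared in either cohort are skipped.  The
    bootstrap resamples SNP pairs (the averaging unit) with percentile
    intervals; windows without a valid pair yield NaN rows with a warning.
    """
    if real.n_sites != synthetic.n_sites:
        raise ValueError("matched site lists are required")
    if not np.array_equal(real.positions, synthetic.positions):
        raise ValueError("site positions differ between cohorts")
    if rng is None:
        rng = np.random.default_rng(0)
    pos = real.positions
    chroms = real.chroms
    r2_real = _r2_matrix(real.rows)
    r2_synth = _r2_matrix(synthetic.rows)
    iu, ju = np.triu_indices(real.n_sites, k=1)
    same = chroms[iu] == chroms[ju]
    dist = pos[ju] - pos[iu]
    err_all = (r2_real[iu, ju] - r2_synth[iu, ju]) ** 2
    records = []
    for w in window_grid:
        keep = same & (dist <= w) & ~np.isnan(err_all)
        err = err_all[keep]
        if err.size == 0:
            warnings.warn(f"no valid SNP pair within window {w} bp", stacklevel=2)
            records.append((w, 0, np.nan, np.nan, np.nan))
            continue
        mse = float(err.mean())
        boots = np.empty(n_boot)
        for b in range(n_boot):
            boots[b] = err[rng.integers(0, err.size, size=err.size)].mean()
        lo, hi = np.percentile(
            boots, [50 * (1 - ci_level), 100 - 50 * (1 - ci_level)]
        )
        records.append((w, int(err.size), mse, float(lo), float(hi)))
    table = pd.DataFrame(
        records, columns=["window_bp", "n_pairs", "mean_sq_error", "ci_low", "ci_high"]
    )
    return LDReport(table=table, n_boot=n_boot, ci_level=ci_level)
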