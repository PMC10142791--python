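"""Community statistics: diversity, rank tests, ordination, summaries.

Shannon diversity is computed over any category set (morphotypes by
default; log base 2). The Kruskal–Wallis H test uses the tie-corrected rank
statistic with a chi-square reference distribution, or an exact permutation
null for small samples. Ordination is a PCA of log10(x+1)-transformed,
standardised variables, with a deterministic component-sign convention.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class StatResult:
    statistic: float
    p_value: float
    df: int
    method: str
    group_sizes: tuple = ()

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p-value outside [0, 1]")


def shannon_index(counts, base: float = 2.0) -> float:
    """Shannon diversity H' = -Σ p_i log_base p_i over nonzero categories."""
    if hasattr(counts, "values") and not isinstance(counts, pd.Series):
        vals = np.asarray(list(counts.values()), dtype=float)
    else:
        vals = np.asarray(counts, dtype=float)
    if vals.size == 0 or vals.sum() <= 0:
        raise ValueError("counts must be nonempty with positive total")
    if np.any(vals < 0):
        raise ValueError("counts must be >= 0")
    p = vals[vals > 0] / vals.sum()
    return float(-np.sum(p * np.log(p) / np.log(base)))


def _h_statistic(groups):
    """Tie-corrected Kruskal–Wallis H for a list of 1-D samples."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(tie_counts**3 - tie_counts) / (n**3 - n)
    if correction == 0:
        raise ValueError("all values identical across groups")
    return h / correction


def kruskal_wallis(groups, p_method: str = "chi2") -> StatResult:
    """Kruskal–Wallis rank test across two or more groups.

    ``p_method='chi2'`` uses the k−1 df chi-square approximation (scipy);
    ``'exact'`` enumerates every assignment of the pooled observations to
    the group sizes (feasible for small total n) and reports the exact
    permutation p-value of the observed H.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    sizes = tuple(len(g) for g in groups)
    dfree = len(groups) - 1
    if np.ptp(np.concatenate(groups)) == 0:
        # identical constant data: no evidence of difference
        return StatResult(0.0, 1.0, dfree, "kruskal-wallis/degenerate", sizes)
    if p_method == "chi2":
        h, p = stats.kruskal(*groups)
        return StatResult(float(h), float(p), dfree, "kruskal-wallis/chi2", sizes)
    if p_method != "exact":
        raise ValueError(f"unknown p_method {p_method!r}")
    pooled = np.concatenate(groups)
    n = pooled.size
    if n > 12:
        raise ValueError("exact permutation null limited to total n <= 12")
    h_obs = _h_statistic(groups)
    idx = range(n)
    count = 0
    total = 0
    for assignment in _group_assignments(idx, sizes):
        gs = [pooled[list(a)] for a in assignment]
        total += 1
        if _h_statistic(gs) >= h_obs - 1e-12:
            count += 1
    return StatResult(float(h_obs), count / total, dfree,
                      "kruskal-wallis/exact-permutation", sizes)


def _group_assignments(indices, sizes):
    """All ways to split ``indices`` into ordered groups of given sizes."""
    indices = tuple(indices)
    if len(sizes) == 1:
        yield (indices,)
        return
    for first in itertools.combinations(indices, sizes[0]):
        rest = tuple(i for i in indices if i not in set(first))
        for tail in _group_assignments(rest, sizes[1:]):
            yield (first,) + tail


@dataclass
class OrdinationResult:
    loadings: pd.DataFrame          # variables × components
    scores: pd.DataFrame            # samples × components
    variance_explained: np.ndarray  # percent per component
    cos2: pd.DataFrame              # squared variable coordinates
    eigenvalues: np.ndarray
    transformed: pd.DataFrame       # the centred/scaled matrix decomposed

    def reconstruction(self) -> np.ndarray:
        return self.scores.to_numpy() @ self.loadings.to_numpy().T


def pca_ordination(matrix: pd.DataFrame, transform: str | None = "log10p1",
                   standardize: bool = True) -> OrdinationResult:
    """PCA of a samples × variables table.

    Variables are log10(x+1)-transformed (the convention for mixed-unit
    environmental data), centred, and scaled to unit variance when
    ``standardize``. Rows with missing values are dropped with a logged
    warning. Component signs are fixed by making each component's
    largest-magnitude loading positive.
    """
    df = pd.DataFrame(matrix).apply(pd.to_numeric)
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        log.warning("dropped %d rows with missing values", n0 - len(df))
    if len(df) < 3 or df.shape[1] < 2:
        raise ValueError("need at least 3 complete samples and 2 variables")
    X = df.to_numpy(dtype=float)
    if transform == "log10p1":
        X = np.log10(X + 1.0)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    X = X - X.mean(axis=0)
    if standardize:
        sd = X.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = df.columns[sd == 0].tolist()
            raise ValueError(f"constant column(s) under standardization: {bad}")
        X = X / sd
    u, s, vt = np.linalg.svd(X, full_matrices=False)
    # deterministic orientation: largest |loading| positive per component
    for j in range(vt.shape[0]):
        k = np.argmax(np.abs(vt[j]))
        if vt[j, k] < 0:
            vt[j] *= -1.0
            u[:, j] *= -1.0
    eig = s**2 / (len(df) - 1)
    var_pct = 100.0 * eig / eig.sum()
    comps = [f"PC{j + 1}" for j in range(len(s))]
    loadings = pd.DataFrame(vt.T, index=df.columns, columns=comps)
    scores = pd.DataFrame(u * s, index=df.index, columns=comps)
    coords = loadings * np.sqrt(eig)
    cos2 = coords**2
    return OrdinationResult(loadings, scores, var_pct, cos2, eig,
                            pd.DataFrame(X, index=df.index, columns=df.columns))


@dataclass
class DistributionSummary:
    mean: float
    sd: float
    median: float
    grid: np.ndarray
    density: np.ndarray
    n: int


def distribution_summary(values, grid_points: int = 256) -> DistributionSummary:
    """Mean/sd/median plus a Gaussian-kernel density curve.

    The density integrates to 1 within 1% on the returned grid (the grid
    spans the data ± 3 bandwidths). A single value yields a narrow bump
    centred on it.
    """
    vals = np.asarray(values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty input")
    mean, sd, med = float(vals.mean()), float(vals.std()), float(np.median(vals))
    if vals.size < 2 or sd == 0:
        bw = max(abs(mean) * 0.01, 1e-3)
        grid = np.linspace(mean - 4 * bw, mean + 4 * bw, grid_points)
        density = stats.norm.pdf(grid, loc=mean, scale=bw)
        return DistributionSummary(mean, sd, med, grid, density, vals.size)
    kde = stats.gaussian_kde(vals)
    bw = kde.factor * sd
    grid = np.linspace(vals.min() - 3 * bw, vals.max() + 3 * bw, grid_points)
    return DistributionSummary(mean, sd, med, grid, kde(grid), vals.size)


def virus_prokaryote_ratio(VA: float, PA: float) -> float:
    """VPR = viral abundance / prokaryotic abundance (both per mL)."""
    if PA <= 0:
        raise ValueError("PA must be > 0")
    if VA < 0:
        raise ValueError("VA must be >= 0")
    return VA / PA
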