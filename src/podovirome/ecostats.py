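"""Mantel permutation tests, paired and two-sample t-tests, correlations.

The Mantel statistic is the Pearson (optionally Spearman) correlation over
the upper-triangle entries of two distance matrices; the null distribution
jointly permutes the rows and columns of the second matrix, and the
one-sided (greater) p-value is (1 + #{r_perm >= r_obs}) / (n_perm + 1), or
the exact enumeration over all n! orderings when requested.  Distances
default to Euclidean on log10(KPKG+1) clade vectors for abundance and
Euclidean on z-scored variables for the environment.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .errors import DegenerateDataError, ParameterError


@dataclass(frozen=True)
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ParameterError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ParameterError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ParameterError("distance matrix must have a zero diagonal")
        if (v < 0).any():
            raise ParameterError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    n_permutations: int | None = None


def euclidean_distance(vectors: pd.DataFrame, zscore: bool = False) -> DistanceMatrix:
    """Euclidean distances between sample rows; optionally z-score columns first."""
    data = vectors.to_numpy(dtype=float)
    if zscore:
        sd = data.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        data = (data - data.mean(axis=0)) / sd
    return DistanceMatrix([str(i) for i in vectors.index], squareform(pdist(data)))


def abundance_distance(kpkg_by_clade: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distance on log10(KPKG + 1) clade vectors (samples x clades)."""
    return euclidean_distance(np.log10(kpkg_by_clade + 1.0))


def _mantel_r(x: np.ndarray, y: np.ndarray, method: str) -> float:
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("constant distance matrix: Mantel r undefined")
    return float(np.corrcoef(x, y)[0, 1])


def mantel(
    dx: DistanceMatrix,
    dy: DistanceMatrix,
    n_perm: int = 999,
    seed: int = 0,
    method: str = "pearson",
    exact: bool = False,
) -> TestResult:
    """One-sided (greater) Mantel test with a seeded permutation null."""
    if dx.labels != dy.labels:
        raise ParameterError("distance matrices must share the same labels, in order")
    n = dx.n
    if n < 4:
        raise ParameterError("Mantel test requires n >= 4")
    if method not in ("pearson", "spearman"):
        raise ParameterError(f"unknown correlation method {method!r}")
    x = dx.condensed()
    r_obs = _mantel_r(x, dy.condensed(), method)
    y_full = dy.values
    if exact:
        perms = list(itertools.permutations(range(n)))
        count = 0
        for p in perms:
            p = np.asarray(p)
            r = _mantel_r(x, y_full[np.ix_(p, p)][np.triu_indices(n, k=1)], method)
            if r >= r_obs - 1e-12:
                count += 1
        return TestResult(r_obs, count / len(perms), n, f"mantel-{method}-exact", len(perms))
    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    count = 0
    for _ in range(n_perm):
        p = rng.permutation(n)
        r = _mantel_r(x, y_full[np.ix_(p, p)][iu], method)
        if r >= r_obs - 1e-12:
            count += 1
    return TestResult(r_obs, (1 + count) / (n_perm + 1), n, f"mantel-{method}", n_perm)


def paired_ttest(surface: np.ndarray, deep: np.ndarray) -> TestResult:
    """Classical paired t-test on site-matched values (two-sided)."""
    surface = np.asarray(surface, dtype=float)
    deep = np.asarray(deep, dtype=float)
    if surface.shape != deep.shape or surface.ndim != 1:
        raise ParameterError("paired samples must be 1-D arrays of equal length")
    n = len(surface)
    if n < 3:
        raise ParameterError("paired t-test requires >= 3 pairs")
    diff = surface - deep
    sd = diff.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("zero-variance differences: paired t undefined")
    t = diff.mean() / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), float(p), n, "paired-t")


def two_sample_ttest(a: np.ndarray, b: np.ndarray, welch: bool = True) -> TestResult:
    """Welch (default) or pooled-variance two-sample t-test, two-sided."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs >= 2 observations")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return TestResult(float(t), float(p), len(a) + len(b), "welch-t" if welch else "pooled-t")


def env_correlations(env: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Pearson r and two-sided p for environmental variables.

    Constant variables get NaN in their row and column.
    """
    cols = list(env.columns)
    k = len(cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    for i in range(k):
        for j in range(i, k):
            pair = env[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                continue
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if x.std() == 0 or y.std() == 0:
                continue
            if i == j:
                r[i, j], p[i, j] = 1.0, 0.0
                continue
            ri, pi = stats.pearsonr(x, y)
            r[i, j] = r[j, i] = ri
            p[i, j] = p[j, i] = pi
    return (
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def significance_stars(p: float) -> str:
    """Figure-legend convention: * <0.05, ** <0.01, *** <0.001, else ns."""
    if math.isnan(p):
        return "na"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """BH-adjusted p-values (optional; the default analysis applies none)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / (np.arange(n) + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adjusted, 1.0)
    return out
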