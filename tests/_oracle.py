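"""Independent brute-force oracles used only by the test suite.

Kept deliberately separate from the package: the oracle implements the same
scoring definitions (local alignment, affine gaps costing open + L * extend)
with plain-Python dynamic programming in a different formulation, so that
agreement with the package's compiled kernel is a meaningful check.
"""

from __future__ import annotations

import itertools

import numpy as np


def gotoh_local_score(
    q: str,
    s: str,
    score_fn,
    gap_open: int,
    gap_extend: int,
) -> int:
    """Best local alignment score under affine gaps; plain-Python DP.

    ``score_fn(a, b)`` gives the substitution score for residues a, b.
    A gap of length L costs gap_open + L * gap_extend.
    """
    n, m = len(q), len(s)
    NEG = float("-inf")
    # rows of the three Gotoh matrices, computed column-major on purpose
    M = [[0.0] * (n + 1) for _ in range(m + 1)]
    X = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in subject (consumes query)
    Y = [[NEG] * (n + 1) for _ in range(m + 1)]  # gap in query (consumes subject)
    best = 0.0
    for j in range(1, m + 1):
        for i in range(1, n + 1):
            X[j][i] = max(M[j][i - 1] - gap_open - gap_extend, X[j][i - 1] - gap_extend)
            Y[j][i] = max(M[j - 1][i] - gap_open - gap_extend, Y[j - 1][i] - gap_extend)
            M[j][i] = max(
                0.0,
                M[j - 1][i - 1] + score_fn(q[i - 1], s[j - 1]),
                X[j][i],
                Y[j][i],
            )
            best = max(best, M[j][i])
    return int(best)


def mantel_exact(dx: np.ndarray, dy: np.ndarray) -> tuple[float, float]:
    """Exact Mantel test by enumerating all n! joint row/column permutations.

    Returns (observed Pearson r over the upper triangle, exact one-sided
    greater p = fraction of orderings with r >= observed).
    """
    n = dx.shape[0]
    iu = np.triu_indices(n, k=1)
    x = dx[iu]

    def corr(m: np.ndarray) -> float:
        y = m[iu]
        return float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )

    r_obs = corr(dy)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = np.asarray(perm)
        total += 1
        if corr(dy[np.ix_(p, p)]) >= r_obs - 1e-12:
            count += 1
    return r_obs, count / total
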