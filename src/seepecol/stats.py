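"""Shared nonparametric statistics.

Thin, contract-enforcing wrappers: Wilcoxon rank-sum and Spearman through
scipy, the Mantel test through scikit-bio (seeded locally), Bonferroni
correction in-package.  Every permutation p-value includes the observed
statistic in the count, so p >= 1/(n_perm + 1) and p = 0 never occurs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as _skbio_mantel

__all__ = [
    "TestResult",
    "wilcoxon_rank_sum",
    "spearman",
    "mantel",
    "bonferroni",
]


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    statistic: float
    p: float
    n: tuple[int, ...]
    method: str
    adjusted_p: float | None = None
    flagged: bool = False  # degenerate input (e.g. zero rank variance)


def wilcoxon_rank_sum(x, y) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) with midrank ties.

    Uses the exact null distribution for small tie-free samples
    (n <= 25 per group) and the normal approximation with continuity
    correction otherwise.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = np.unique(np.concatenate([x, y])).size < x.size + y.size
    method = "exact" if (x.size <= 25 and y.size <= 25 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        float(res.statistic), float(res.pvalue), (x.size, y.size),
        f"wilcoxon_rank_sum[{method}]",
    )


def spearman(x, y, n_permutations: int | None = None, seed: int = 0) -> TestResult:
    """Spearman rank correlation (midranks); t-approximation p, or a
    permutation p when ``n_permutations`` is given (recommended for n < 10)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("need n >= 4 for Spearman correlation")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return TestResult(float("nan"), float("nan"), (x.size,),
                          "spearman", flagged=True)
    rho, p = sps.spearmanr(x, y)
    if n_permutations:
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_permutations):
            r_perm, _ = sps.spearmanr(x, rng.permutation(y))
            if abs(r_perm) >= abs(rho):
                count += 1
        p = (count + 1.0) / (n_permutations + 1.0)
        return TestResult(float(rho), float(p), (x.size,), "spearman[permutation]")
    return TestResult(float(rho), float(p), (x.size,), "spearman[t-approx]")


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    n_permutations: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> TestResult:
    """Mantel test between two distance matrices over the same samples.

    Correlation (Spearman by default) over the lower triangles; p by joint
    row/column permutation of one matrix, observed labelling included in the
    count.
    """
    if set(d1.ids) != set(d2.ids):
        raise ValueError("distance matrices must cover the same samples")
    d2 = d2.filter(d1.ids)
    state = np.random.get_state()
    try:
        np.random.seed(seed % (2**32))
        r, p, n = _skbio_mantel(
            d1, d2, method=method, permutations=n_permutations, alternative="two-sided"
        )
    finally:
        np.random.set_state(state)
    return TestResult(float(r), float(p), (int(n),), f"mantel[{method}]")


def bonferroni(p_values) -> list[float]:
    """Bonferroni adjustment: min(1, p * m)."""
    ps = list(p_values)
    m = len(ps)
    for p in ps:
        if not (0.0 < p <= 1.0):
            raise ValueError("p-values must lie in (0, 1]")
    return [min(1.0, p * m) for p in ps]
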