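"""Between-site comparison of monitoring series via the Mann-Whitney U test.

Small, tie-free samples get an exact p-value by full enumeration of rank
assignments under the null; larger or tied samples use the normal
approximation with tie-corrected variance and continuity correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError

EXACT_LIMIT = 16  # exact enumeration up to n1 + n2 of this size (C(16,8)=12870)


@dataclass(frozen=True)
class UTestResult:
    U: float          # min(U1, U2)
    p_two_sided: float
    method: str       # "exact" | "normal_approx"
    n1: int
    n2: int


def _u_statistics(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """U1 (for x) and U2 from midrank sums of the pooled sample."""
    n1, n2 = len(x), len(y)
    ranks = stats.rankdata(np.concatenate([x, y]))
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    return u1, n1 * n2 - u1


def _exact_p(u_obs: float, n1: int, n2: int) -> float:
    """Two-sided exact p: twice the one-tail probability P(U1 <= u_obs)
    under random rank assignment (U1's null distribution is symmetric, so
    either tail doubles to the same value), capped at 1.  Tie-free only."""
    n = n1 + n2
    total = comb(n, n1)
    offset = n1 * (n1 + 1) // 2
    count = 0
    for ranks_x in combinations(range(1, n + 1), n1):
        u1 = sum(ranks_x) - offset
        if u1 <= u_obs + 1e-9:
            count += 1
    return min(1.0, 2.0 * count / total)


def _normal_approx_p(u: float, n1: int, n2: int, pooled: np.ndarray) -> float:
    n = n1 + n2
    mean = n1 * n2 / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    # U = min(U1, U2) <= mean; continuity-correct toward the mean
    z = (u - mean + 0.5) / sqrt(var)
    return min(1.0, 2.0 * float(stats.norm.cdf(z)))


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> UTestResult:
    """Two-sided Mann-Whitney U test.

    Reports U = min(U1, U2) from midrank sums.  Exact enumeration of all
    C(n1+n2, n1) rank assignments when the pooled sample is tie-free and no
    larger than 16; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValidationError("both samples must be non-empty")
    u1, u2 = _u_statistics(x, y)
    u = min(u1, u2)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < n1 + n2
    if not has_ties and n1 + n2 <= EXACT_LIMIT:
        p = _exact_p(u, n1, n2)
        method = "exact"
    else:
        p = _normal_approx_p(u, n1, n2, pooled)
        method = "normal_approx"
    return UTestResult(U=float(u), p_two_sided=p, method=method, n1=n1, n2=n2)


def compare_sites(
    series_a: "Sequence[tuple[int, float]]",
    series_b: "Sequence[tuple[int, float]]",
    common_years_only: bool = True,
) -> UTestResult:
    """Compare two (year, value) series between sites, unpaired.

    By default restricts both to the overlapping year range so neither site
    is advantaged by years the other did not sample; values are then pooled
    unpaired into the U test.
    """
    a = list(series_a)
    b = list(series_b)
    if common_years_only and a and b:
        lo = max(min(y for y, _ in a), min(y for y, _ in b))
        hi = min(max(y for y, _ in a), max(y for y, _ in b))
        a = [(y, v) for y, v in a if lo <= y <= hi]
        b = [(y, v) for y, v in b if lo <= y <= hi]
    if not a or not b:
        raise ValidationError("no overlapping years between the two series")
    return mann_whitney([v for _, v in a], [v for _, v in b])
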