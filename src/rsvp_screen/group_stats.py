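"""Nonparametric two-group comparison.

The group comparison uses the Mann-Whitney U test with midranks for ties.
For the sample sizes involved here (n_ci + n_hc = 22) the two-sided p-value
is computed by *exact enumeration*: the null distribution of U is obtained
by counting, over all C(N, n_ci) assignments of the observed midranks to the
CI group, how many rank sums are attainable (a subset-sum dynamic programme
over doubled midranks, so ties cost nothing).  Beyond ``exact_limit`` total
observations the tie- and continuity-corrected normal approximation from
scipy is used instead; the method is recorded in the result.

The accompanying effect size is the common-language effect size (CLES): the
probability that a randomly drawn HC score exceeds a randomly drawn CI
score, ties counted half — identical to U_hc / (n_ci * n_hc).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import EmptySampleError, InvalidUError

EXACT_LIMIT_DEFAULT = 25


@dataclass(frozen=True)
class MWUResult:
    """Mann-Whitney comparison of a CI sample against an HC sample.

    ``u_reported`` follows the convention of reporting min(U_ci, U_hc);
    ``effect_size`` is the CLES with HC as the hypothesised-superior group.
    """

    u_ci: float
    u_hc: float
    u_reported: float
    p_two_sided: float
    effect_size: float
    method: str  # "exact_enumeration" | "normal_approx"


def _u_statistics(x_ci, x_hc) -> tuple[float, float, np.ndarray]:
    """(u_ci, u_hc, midranks of the pooled sample)."""
    x_ci = np.asarray(x_ci, dtype=float)
    x_hc = np.asarray(x_hc, dtype=float)
    n1, n2 = len(x_ci), len(x_hc)
    ranks = stats.rankdata(np.concatenate([x_ci, x_hc]))
    u_ci = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    u_hc = n1 * n2 - u_ci
    return u_ci, u_hc, ranks


def _exact_u1_distribution(midranks: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of U1 over all size-n1 subsets of the midranks.

    Returns (doubled U1 values, counts).  Midranks are doubled so the
    subset-sum DP runs on integers; counts stay exact in float64 up to
    C(25, 12) and far beyond.
    """
    doubled = np.rint(2 * midranks).astype(np.int64)
    total = int(doubled.sum())
    dp = np.zeros((n1 + 1, total + 1))
    dp[0, 0] = 1.0
    for i, r in enumerate(doubled):
        for k in range(min(i + 1, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : total + 1 - r]
    counts = dp[n1]
    support = np.nonzero(counts)[0]
    # doubled U1 = doubled rank sum - n1*(n1+1)
    return support - n1 * (n1 + 1), counts[support]


def mann_whitney(
    x_ci, x_hc, *, exact_limit: int = EXACT_LIMIT_DEFAULT
) -> MWUResult:
    """Two-sided Mann-Whitney U test of CI vs HC scores.

    Exact enumeration (conditional on the observed tie pattern) when
    ``len(x_ci) + len(x_hc) <= exact_limit``; otherwise the corrected
    normal approximation.  The two-sided exact p-value is
    P(U <= u_min) + P(U >= n1*n2 - u_min), capped at 1.
    """
    x_ci = np.asarray(x_ci, dtype=float)
    x_hc = np.asarray(x_hc, dtype=float)
    if len(x_ci) == 0 or len(x_hc) == 0:
        raise EmptySampleError("both samples must be non-empty")
    n1, n2 = len(x_ci), len(x_hc)
    u_ci, u_hc, ranks = _u_statistics(x_ci, x_hc)
    u_min = min(u_ci, u_hc)

    if n1 + n2 <= exact_limit:
        u_vals2, counts = _exact_u1_distribution(ranks, n1)
        total = counts.sum()
        lo2 = int(round(2 * u_min))
        hi2 = 2 * n1 * n2 - lo2
        p = (counts[u_vals2 <= lo2].sum() + counts[u_vals2 >= hi2].sum()) / total
        p = float(min(p, 1.0))
        method = "exact_enumeration"
    else:
        res = stats.mannwhitneyu(
            x_ci, x_hc, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        p = float(res.pvalue)
        method = "normal_approx"

    return MWUResult(
        u_ci=u_ci,
        u_hc=u_hc,
        u_reported=u_min,
        p_two_sided=p,
        effect_size=u_hc / (n1 * n2),
        method=method,
    )


def cles(x_ci, x_hc) -> float:
    """Common-language effect size: P(HC > CI) + 0.5 * P(HC = CI)."""
    x_ci = np.asarray(x_ci, dtype=float)
    x_hc = np.asarray(x_hc, dtype=float)
    if len(x_ci) == 0 or len(x_hc) == 0:
        raise EmptySampleError("both samples must be non-empty")
    _, u_hc, _ = _u_statistics(x_ci, x_hc)
    return u_hc / (len(x_ci) * len(x_hc))


def cles_from_u(u_reported: float, n_ci: int, n_hc: int) -> float:
    """Recover the CLES from a reported (minimum-convention) U statistic.

    With U reported as the smaller of the two statistics — the CI group's U
    when HC scores higher — the effect size is 1 - U / (n_ci * n_hc).
    """
    nn = n_ci * n_hc
    if not 0 <= u_reported <= nn:
        raise InvalidUError(f"U={u_reported} outside [0, {nn}]")
    return 1.0 - u_reported / nn


def sem(x) -> float:
    """Standard error of the mean: sample sd (n-1 denominator) / sqrt(n)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        raise EmptySampleError("SEM needs at least two observations")
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))
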