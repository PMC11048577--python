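"""Univariate screening of candidate IDH-status predictors.

Two tests, implemented from first principles rather than delegated:
Pearson's chi-squared (no continuity correction) for the binary flags and
the Mann-Whitney U test for the continuous markers.  Screening flags a
marker as a candidate predictor at unadjusted two-sided p < 0.05, mirroring
the published analysis; no multiple-testing correction is applied (a
documented limitation of the screening design, not an oversight).

The U statistic uses the pair-counting definition with ties counted 1/2, so
U / (n1 * n2) is exactly the empirical ROC AUC computed elsewhere in this
package — that identity is enforced by a cross-module test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .cohort import BINARY_MARKERS, CONTINUOUS_MARKERS, PatientRecord, cohort_to_frame

__all__ = ["TestResult", "pearson_chi2_2x2", "mann_whitney_u", "screen_parameters"]

#: Largest n1*n2 for which the exact null distribution of U is enumerated.
EXACT_LIMIT = 400


@dataclass(frozen=True)
class TestResult:
    """Outcome of one univariate screen.

    ``direction`` names the group with the larger location (continuous) or
    proportion (binary); by package convention the first sample / first row
    passed to the test functions is the IDH-mutant group.
    """

    marker: str
    method: Literal["pearson_chi2", "mann_whitney_u"]
    statistic: float
    p_value: float
    direction: Literal["mut", "wt", "tie"]
    n_mut: int
    n_wt: int
    significant: bool | None = None


def pearson_chi2_2x2(a: int, b: int, c: int, d: int) -> TestResult:
    """Pearson chi-squared test on a 2x2 table, df = 1, no Yates correction.

    Rows are groups (first row IDH-mut by convention), columns are
    flag-present / flag-absent: ``[[a, b], [c, d]]``.  The statistic is
    sum (O - E)^2 / E, equal to n (ad - bc)^2 / (r1 r2 c1 c2); the two-sided
    p-value comes from the chi-squared(1) survival function.
    """
    counts = np.array([[a, b], [c, d]], dtype=float)
    if (counts < 0).any() or not np.all(counts == np.floor(counts)):
        raise ValueError("cell counts must be non-negative integers")
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    if min(r1, r2, c1, c2) == 0:
        raise ValueError("zero margin: expected counts undefined for this table")
    n = r1 + r2
    statistic = n * (a * d - b * c) ** 2 / (r1 * r2 * c1 * c2)
    p1, p2 = a / r1, c / r2
    direction = "mut" if p1 > p2 else ("wt" if p2 > p1 else "tie")
    return TestResult(
        marker="",
        method="pearson_chi2",
        statistic=float(statistic),
        p_value=float(stats.chi2.sf(statistic, df=1)),
        direction=direction,
        n_mut=int(r1),
        n_wt=int(r2),
    )


def _rank_sum_null_counts(n1: int, n: int) -> np.ndarray:
    """Counts of rank-sum values over all C(n, n1) subsets of ranks 1..n.

    Classic subset-sum dynamic programme; index u of the returned vector is
    the rank sum of the first sample.
    """
    max_sum = n1 * n
    dp = np.zeros((n1 + 1, max_sum + 1))
    dp[0, 0] = 1.0
    for r in range(1, n + 1):
        for m in range(min(n1, r), 0, -1):
            dp[m, r:] += dp[m - 1, : max_sum + 1 - r]
    return dp[n1]


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    """P(|U - n1 n2 / 2| >= |u - n1 n2 / 2|) under the tie-free null."""
    counts = _rank_sum_null_counts(n1, n1 + n2)
    u_all = np.arange(counts.size) - n1 * (n1 + 1) / 2  # rank sum -> U
    dev = abs(u - n1 * n2 / 2)
    p = counts[np.abs(u_all - n1 * n2 / 2) >= dev - 1e-9].sum() / counts.sum()
    return float(min(1.0, p))


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann-Whitney U test; first sample is IDH-mut by convention.

    The statistic is U for ``x``: the number of (x, y) pairs with x > y,
    ties counted 1/2.  The p-value is exact (full enumeration of the null
    distribution) when n1*n2 <= 400 and the pooled data are tie-free;
    otherwise a normal approximation with tie-corrected variance and a 0.5
    continuity correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())
    n = n1 + n2
    if not has_ties and n1 * n2 <= EXACT_LIMIT:
        p = _exact_two_sided_p(u, n1, n2)
    else:
        tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if var <= 0:  # all pooled values identical
            p = 1.0
        else:
            z = max(0.0, abs(u - n1 * n2 / 2.0) - 0.5) / np.sqrt(var)
            p = float(min(1.0, 2.0 * stats.norm.sf(z)))
    mid = n1 * n2 / 2.0
    direction = "mut" if u > mid else ("wt" if u < mid else "tie")
    return TestResult(
        marker="",
        method="mann_whitney_u",
        statistic=u,
        p_value=p,
        direction=direction,
        n_mut=n1,
        n_wt=n2,
    )


def screen_parameters(
    cohort: Sequence[PatientRecord], alpha: float = 0.05
) -> list[TestResult]:
    """Screen every marker against the IDH label of a labelled cohort.

    Continuous markers are compared with the Mann-Whitney U test, binary
    flags (seven locations plus sex) with Pearson's chi-squared test.
    Results are sorted by marker name and flagged significant at ``alpha``
    (default 0.05, the published screening threshold).

    A binary flag that is constant across the whole cohort yields an
    undefined chi-squared table; such markers are reported with statistic 0
    and p = 1 (no evidence of association) rather than raising.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    frame = cohort_to_frame(cohort)
    if (frame["idh_status"] == "unknown").any():
        raise ValueError("screening requires every record to carry an IDH label")
    mut = frame[frame["idh_status"] == "mut"]
    wt = frame[frame["idh_status"] == "wt"]
    if len(mut) == 0 or len(wt) == 0:
        raise ValueError("cohort must contain both IDH classes")

    results: list[TestResult] = []
    for name in CONTINUOUS_MARKERS:
        res = mann_whitney_u(mut[name].to_numpy(), wt[name].to_numpy())
        results.append(replace(res, marker=name, significant=res.p_value < alpha))
    for name in BINARY_MARKERS:
        a = int(mut[name].sum())
        b = len(mut) - a
        c = int(wt[name].sum())
        d = len(wt) - c
        try:
            res = pearson_chi2_2x2(a, b, c, d)
        except ValueError:
            res = TestResult(
                marker=name,
                method="pearson_chi2",
                statistic=0.0,
                p_value=1.0,
                direction="tie",
                n_mut=len(mut),
                n_wt=len(wt),
            )
        results.append(replace(res, marker=name, significant=res.p_value < alpha))
    return sorted(results, key=lambda r: r.marker)
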