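"""Small-sample statistics: exact Wilcoxon tests, paired t-test, SEM.

Cohorts of 5 + 5 animals are far below the regime where normal
approximations are trustworthy, so the two-group comparison defaults to the
exact Wilcoxon rank-sum (Mann–Whitney) test with the null distribution
enumerated over all C(n₁+n₂, n₁) group assignments.  The Wilcoxon
signed-rank test (exact over all 2ⁿ sign patterns) is provided for paired
designs, and the paired-samples t-test for cell-line replicate experiments.

Note on test naming: comparing two independent groups of animals calls for
the rank-sum test; the signed-rank test is its paired counterpart.  Both are
implemented so either convention found in the literature can be reproduced.

No multiple-testing correction is applied across days; per-day p-values are
reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .quantify import CohortTable

__all__ = [
    "TestResult",
    "paired_t_test",
    "wilcoxon_rank_sum",
    "wilcoxon_signed_rank",
    "sem",
    "compare_groups_by_day",
]

#: largest pooled size for which the rank-sum null is fully enumerated
EXACT_RANKSUM_LIMIT = 12
#: largest number of nonzero differences for which sign patterns are enumerated
EXACT_SIGNEDRANK_LIMIT = 15


@dataclass
class TestResult:
    statistic: float
    p_value: float
    method: str
    exact: bool
    n: tuple[int, ...]
    sidedness: str = "two-sided"
    warning: str | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")


def sem(values) -> float:
    """Standard error of the mean: sd (denominator n−1) / √n."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("SEM needs at least 2 values")
    return float(values.std(ddof=1) / np.sqrt(values.size))


def paired_t_test(x, y) -> TestResult:
    """Two-sided paired-samples t-test on differences x − y.

    t = mean(d) / (sd(d)/√n) with sd using n−1; p from Student's t with
    n−1 degrees of freedom.  Degenerate zero-variance cases: all-equal pairs
    give t = 0, p = 1; constant nonzero differences give p = 0 with a
    warning flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs n ≥ 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return TestResult(0.0, 1.0, "paired t-test", False, (n,))
        return TestResult(
            np.inf if d.mean() > 0 else -np.inf,
            0.0,
            "paired t-test",
            False,
            (n,),
            warning="zero variance with nonzero mean difference",
        )
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return TestResult(float(t), float(min(p, 1.0)), "paired t-test", False, (n,))


@lru_cache(maxsize=256)
def _ranksum_null(doubled_ranks: tuple[int, ...], n1: int) -> np.ndarray:
    """Null distribution of 2·W over all C(n, n1) group assignments.

    Keyed by the (sorted) doubled midranks, so repeated tests on tie-free
    data of the same sizes reuse one enumeration.
    """
    r2 = np.array(doubled_ranks, dtype=np.int64)
    return np.array(
        [r2[list(idx)].sum() for idx in combinations(range(r2.size), n1)],
        dtype=np.int64,
    )


@lru_cache(maxsize=256)
def _signedrank_null(doubled_ranks: tuple[int, ...]) -> np.ndarray:
    """Null distribution of 2·W⁺ over all 2ⁿ sign patterns."""
    r2 = np.array(doubled_ranks, dtype=np.int64)
    n = r2.size
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(bool)
    return signs @ r2


def _exact_two_sided(null_doubled: np.ndarray, observed_doubled: int) -> float:
    """min(1, 2·min(P(W ≤ w), P(W ≥ w))) over an enumerated null.

    Statistics are passed doubled and rounded to integers so midrank halves
    compare exactly.
    """
    lo = np.count_nonzero(null_doubled <= observed_doubled)
    hi = np.count_nonzero(null_doubled >= observed_doubled)
    total = null_doubled.size
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_rank_sum(group1, group2, mode: str = "auto") -> TestResult:
    """Two-sided Wilcoxon rank-sum test; W = rank sum of ``group1``.

    Ties receive midranks.  ``mode`` is ``auto`` (exact when
    n₁+n₂ ≤ 12 and the pooled data are tie-free, else normal), ``exact``
    (full enumeration of all C(n₁+n₂, n₁) assignments; valid with ties as a
    permutation test on midranks) or ``normal`` (tie-corrected normal
    approximation with continuity correction).
    """
    g1 = np.asarray(group1, dtype=float).ravel()
    g2 = np.asarray(group2, dtype=float).ravel()
    n1, n2 = g1.size, g2.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([g1, g2])
    n = n1 + n2
    ranks = sps.rankdata(pooled)  # midranks
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < n

    if mode == "auto":
        mode = "exact" if (n <= EXACT_RANKSUM_LIMIT and not has_ties) else "normal"
    if mode == "exact":
        # doubled ranks are exact integers even with midrank halves
        r2 = np.rint(2 * ranks).astype(np.int64)
        null = _ranksum_null(tuple(sorted(r2)), n1)
        p = _exact_two_sided(null, int(np.rint(2 * w)))
        return TestResult(w, p, "Wilcoxon rank-sum (exact)", True, (n1, n2))
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    mean = n1 * (n + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * (n + 1 - tie_term)
    if var <= 0:  # all pooled values identical
        return TestResult(w, 1.0, "Wilcoxon rank-sum (normal approx.)", False, (n1, n2))
    # continuity correction toward the null mean
    z = (w - mean - 0.5 * np.sign(w - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w, float(p), "Wilcoxon rank-sum (normal approx.)", False, (n1, n2))


def wilcoxon_signed_rank(
    diffs, mode: str = "auto", zero_method: str = "wilcoxon"
) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    W⁺ is the sum of the |d| midranks of the positive differences.  Zeros
    are dropped before ranking (``zero_method="wilcoxon"``, the default) or
    ranked and then discarded (``"pratt"``).  Exact mode enumerates all 2ⁿ
    sign patterns (default for n ≤ 15 nonzero differences); otherwise a
    tie-corrected normal approximation with continuity correction is used.
    """
    d = np.asarray(diffs, dtype=float).ravel()
    if d.size == 0:
        raise ValueError("empty difference vector")
    if zero_method not in ("wilcoxon", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    nonzero = d != 0
    if not nonzero.any():
        raise ValueError("all differences are zero; signed-rank test undefined")
    if zero_method == "wilcoxon":
        d = d[nonzero]
        ranks = sps.rankdata(np.abs(d))
    else:  # pratt: zeros participate in ranking, then drop
        ranks = sps.rankdata(np.abs(d))
        ranks = ranks[nonzero]
        d = d[nonzero]
    n = d.size
    w_plus = float(ranks[d > 0].sum())

    if mode == "auto":
        mode = "exact" if n <= EXACT_SIGNEDRANK_LIMIT else "normal"
    if mode == "exact":
        r2 = np.rint(2 * ranks).astype(np.int64)
        null = _signedrank_null(tuple(sorted(r2)))
        p = _exact_two_sided(null, int(np.rint(2 * w_plus)))
        return TestResult(w_plus, p, "Wilcoxon signed-rank (exact)", True, (n,))
    if mode != "normal":
        raise ValueError(f"unknown mode {mode!r}")
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(np.abs(d), return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - float((counts**3 - counts).sum()) / 48.0
    if var <= 0:
        return TestResult(w_plus, 1.0, "Wilcoxon signed-rank (normal approx.)", False, (n,))
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / np.sqrt(var)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return TestResult(w_plus, float(p), "Wilcoxon signed-rank (normal approx.)", False, (n,))


def _auc(measurements: dict[int, float]) -> float:
    days = sorted(measurements)
    values = [measurements[d] for d in days]
    return float(np.trapezoid(values, days))


def compare_groups_by_day(
    cohort: CohortTable,
    method: str = "ranksum",
    mode: str = "auto",
    alpha: float = 0.05,
    days: list[int] | None = None,
) -> pd.DataFrame:
    """Per-day two-group comparison table.

    ``method`` is ``ranksum`` (default, independent groups), ``signedrank``
    (pairs animals by within-group order; requires equal group sizes) or
    ``auc`` (a single rank-sum test on per-animal area under the burden
    curve, reported with day = -1).  Columns: day, n_vehicle, n_treated,
    statistic, p_value, method, exact, significant (p < alpha).
    """
    if method == "auc":
        v = [_auc(a.measurements) for a in cohort.group("vehicle")]
        t = [_auc(a.measurements) for a in cohort.group("treated")]
        res = wilcoxon_rank_sum(v, t, mode=mode)
        rows = [
            {
                "day": -1,
                "n_vehicle": len(v),
                "n_treated": len(t),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method + " on AUC",
                "exact": res.exact,
                "significant": res.p_value < alpha,
            }
        ]
        return pd.DataFrame(rows)

    rows = []
    for day in days if days is not None else cohort.days:
        v = cohort.group_values("vehicle", day)
        t = cohort.group_values("treated", day)
        if v.size == 0 or t.size == 0:
            continue
        if method == "ranksum":
            res = wilcoxon_rank_sum(v, t, mode=mode)
        elif method == "signedrank":
            if v.size != t.size:
                raise ValueError("signed-rank pairing needs equal group sizes")
            res = wilcoxon_signed_rank(v - t, mode=mode)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append(
            {
                "day": day,
                "n_vehicle": int(v.size),
                "n_treated": int(t.size),
                "statistic": res.statistic,
                "p_value": res.p_value,
                "method": res.method,
                "exact": res.exact,
                "significant": res.p_value < alpha,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "day",
            "n_vehicle",
            "n_treated",
            "statistic",
            "p_value",
            "method",
            "exact",
            "significant",
        ],
    )
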