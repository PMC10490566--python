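"""Session analytics: a from-scratch Mann-Whitney U test and condition summaries.

The rank-sum test is implemented here rather than delegated because it is the
inferential core of the three-condition comparison: U is computed from
midranks, the p-value is exact (enumeration of rank assignments, or the
classical rank-sum counting recursion when the pooled data are tie-free) for
small samples and a tie-corrected normal approximation with continuity
correction otherwise.  Two-sided p-values double the smaller one-sided tail,
capped at 1.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
from functools import lru_cache
from scipy.special import ndtr

EXACT_MAX_N = 12          # auto method switches to the normal approximation above this
_ENUM_MAX_N = 20          # hard cap for tied-data enumeration
_EPS = 1e-9


@dataclass(frozen=True)
class MannWhitneyResult:
    u_x: float
    u_y: float
    p_two_sided: float
    method: str               # "exact" | "normal"


def _midranks(pooled: np.ndarray) -> np.ndarray:
    """Ranks 1..N with ties sharing their average rank."""
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=64)
def _exact_distribution_tie_free(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of rank assignments giving U = u (no ties).

    Classical rank-sum counting: tabulate the number of size-n1 subsets of
    the ranks {1..N} by subset rank-sum, then shift by n1(n1+1)/2 to get U.
    """
    n = n1 + n2
    offset = n1 * (n1 + 1) // 2
    max_sum = sum(range(n - n1 + 1, n + 1))
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=float)
    ways[0, 0] = 1.0
    for r in range(1, n + 1):
        for i in range(min(r, n1), 0, -1):
            ways[i, r:] += ways[i - 1, :max_sum + 1 - r]
    counts = np.zeros(n1 * n2 + 1, dtype=float)
    for s in range(offset, max_sum + 1):
        counts[s - offset] = ways[n1, s]
    return counts


def _exact_tail_probs(x: np.ndarray, y: np.ndarray, u_obs: float) -> tuple[float, float]:
    """P(U >= u_obs) and P(U <= u_obs) over all rank assignments.

    Tie-free data use the counting recursion; tied data enumerate all
    C(N, n1) assignments of the pooled midranks.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    if len(np.unique(pooled)) == len(pooled):
        counts = _exact_distribution_tie_free(n1, n2)
        total = counts.sum()
        u_grid = np.arange(len(counts))
        p_ge = counts[u_grid >= u_obs - _EPS].sum() / total
        p_le = counts[u_grid <= u_obs + _EPS].sum() / total
        return float(p_ge), float(p_le)
    if n1 + n2 > _ENUM_MAX_N:
        raise ValueError(f"exact test with ties limited to N <= {_ENUM_MAX_N}")
    ranks = _midranks(pooled)
    offset = n1 * (n1 + 1) / 2.0
    n_ge = n_le = total = 0
    for idx in combinations(range(n1 + n2), n1):
        u = sum(ranks[i] for i in idx) - offset
        total += 1
        if u >= u_obs - _EPS:
            n_ge += 1
        if u <= u_obs + _EPS:
            n_le += 1
    return n_ge / total, n_le / total


def mann_whitney_u(x, y, method: str = "auto") -> MannWhitneyResult:
    """Two-sided Mann-Whitney U test of two independent samples.

    U_x counts pairs (x_i, y_j) with x_i > y_j (ties count half), computed
    via midranks; U_x + U_y = n_x * n_y.  ``method`` is "exact",
    "normal", or "auto" (exact when n_x + n_y <= 12).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 1 or n2 < 1:
        raise ValueError("both samples must be non-empty")
    if method not in ("auto", "exact", "normal"):
        raise ValueError("method must be auto | exact | normal")
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u_x = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    u_y = float(n1 * n2 - u_x)

    use_exact = method == "exact" or (method == "auto" and n1 + n2 <= EXACT_MAX_N)
    if use_exact:
        p_ge, p_le = _exact_tail_probs(x, y, u_x)
        p = min(1.0, 2.0 * min(p_ge, p_le))
        return MannWhitneyResult(u_x, u_y, p, "exact")

    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))) if n > 1 else 0.0
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return MannWhitneyResult(u_x, u_y, 1.0, "normal")
    diff = u_x - mu
    z = (diff - 0.5 * math.copysign(1.0, diff)) / math.sqrt(var) if diff != 0 else 0.0
    p = min(1.0, 2.0 * float(ndtr(-abs(z))))
    return MannWhitneyResult(u_x, u_y, p, "normal")


@dataclass(frozen=True)
class ConditionSummary:
    """Box-plot statistics of one condition plus its test against the reference."""

    condition: str
    n: int
    median_s: float
    q1_s: float
    q3_s: float
    whisker_low_s: float
    whisker_high_s: float
    outliers_s: tuple[float, ...]
    u_stat: float | None = None        # vs the reference condition
    p_two_sided: float | None = None
    reference: str | None = None


def _durations_by_condition(records) -> dict[str, np.ndarray]:
    groups: dict[str, list[float]] = {}
    for rec in records:
        cond = getattr(rec, "condition", None)
        if not cond:
            raise ValueError("record without a condition label")
        groups.setdefault(cond, []).append(float(rec.good_duration_s))
    return {c: np.array(v) for c, v in groups.items()}


def tukey_outliers(values: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Tukey fences (q1 - 1.5 IQR, q3 + 1.5 IQR) and the values beyond them."""
    q1, q3 = np.percentile(values, [25, 75])  # linear-interpolation quartiles
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return lo, hi, values[(values < lo) | (values > hi)]


def summarize_conditions(records, reference: str = "NFB",
                         method: str = "auto") -> list[ConditionSummary]:
    """Per-condition box statistics and rank-sum tests against ``reference``.

    Outliers follow the 1.5 IQR rule; whiskers extend to the most extreme
    non-outlying values.  With a single condition (or a missing reference)
    summaries carry no tests.
    """
    groups = _durations_by_condition(records)
    for cond, vals in groups.items():
        if len(vals) < 2:
            raise ValueError(f"need >= 2 records per condition ({cond} has {len(vals)})")
    ref_vals = groups.get(reference)
    summaries = []
    for cond in sorted(groups):
        vals = groups[cond]
        q1, med, q3 = np.percentile(vals, [25, 50, 75])
        lo, hi, outliers = tukey_outliers(vals)
        inliers = vals[(vals >= lo) & (vals <= hi)]
        u = p = None
        if ref_vals is not None and cond != reference and len(groups) > 1:
            res = mann_whitney_u(vals, ref_vals, method=method)
            u, p = res.u_x, res.p_two_sided
        summaries.append(ConditionSummary(
            condition=cond, n=len(vals), median_s=float(med),
            q1_s=float(q1), q3_s=float(q3),
            whisker_low_s=float(inliers.min()), whisker_high_s=float(inliers.max()),
            outliers_s=tuple(sorted(float(v) for v in outliers)),
            u_stat=u, p_two_sided=p,
            reference=reference if u is not None else None))
    return summaries


def write_boxplot_data(summaries: list[ConditionSummary], path: str | Path) -> None:
    """Emit the box-plot data file (JSON) for external plotting."""
    payload = [{"condition": s.condition, "n": s.n, "median_s": s.median_s,
                "q1_s": s.q1_s, "q3_s": s.q3_s,
                "whisker_low_s": s.whisker_low_s, "whisker_high_s": s.whisker_high_s,
                "outliers_s": list(s.outliers_s), "u_stat": s.u_stat,
                "p_two_sided": s.p_two_sided, "reference": s.reference}
               for s in summaries]
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
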