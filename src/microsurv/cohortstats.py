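"""Cohort baseline comparisons: Fisher's exact test for categorical variables
and the Wilcoxon rank-sum test for continuous ones, plus a Table-1-style
summary grouped by progression status.

Two-sided Fisher p-values use the probability-mass convention: the p-value is
the total probability, under the hypergeometric null with fixed margins, of
all tables no more probable than the observed one (with a small floating-point
tolerance for ties). For 2 x k tables with k > 2 the Freeman-Halton extension
is computed by full enumeration of the margin-constrained support, which is
feasible at cohort scale.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

_PROB_TOL_FACTOR = 1 + 1e-7


def _validate_table(table) -> np.ndarray:
    arr = np.asarray(table)
    if arr.ndim != 2 or arr.shape[0] != 2 or arr.shape[1] < 2:
        raise ValueError("contingency table must be 2 x k with k >= 2")
    if not np.all(np.equal(np.mod(arr, 1), 0)) or (arr < 0).any():
        raise ValueError("contingency table must hold nonnegative integer counts")
    arr = arr.astype(np.int64)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all table margins must be positive")
    return arr


def _log_table_prob(row0: tuple[int, ...], col_sums: np.ndarray, n0: int, n1: int,
                    log_fact: np.ndarray, log_denom: float) -> float:
    """Log hypergeometric probability of a 2 x k table given its margins."""
    lp = log_fact[n0] + log_fact[n1] + log_fact[col_sums].sum() - log_denom
    for j, c in enumerate(col_sums):
        a = row0[j]
        lp -= log_fact[a] + log_fact[c - a]
    return lp


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p-value for a 2 x k contingency table.

    2 x 2 tables use the exact hypergeometric computation; wider tables use
    the Freeman-Halton extension via full enumeration.
    """
    arr = _validate_table(table)
    if arr.shape[1] == 2:
        return float(stats.fisher_exact(arr, alternative="two-sided")[1])

    col_sums = arr.sum(axis=0)
    n0 = int(arr.sum(axis=1)[0])
    n1 = int(arr.sum(axis=1)[1])
    n = n0 + n1
    log_fact = np.concatenate([[0.0], np.cumsum(np.log(np.arange(1, n + 1)))])
    log_denom = log_fact[n]

    obs_lp = _log_table_prob(tuple(arr[0]), col_sums, n0, n1, log_fact, log_denom)
    threshold = obs_lp + math.log(_PROB_TOL_FACTOR)

    k = len(col_sums)
    p_total = 0.0

    def recurse(j: int, remaining: int, row0: list[int]) -> None:
        nonlocal p_total
        if j == k - 1:
            if remaining <= col_sums[j]:
                lp = _log_table_prob(tuple(row0 + [remaining]), col_sums, n0, n1,
                                     log_fact, log_denom)
                if lp <= threshold:
                    p_total += math.exp(lp)
            return
        lo = max(0, remaining - int(col_sums[j + 1:].sum()))
        hi = min(int(col_sums[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, row0 + [a])

    recurse(0, n0, [])
    return float(min(p_total, 1.0))


def wilcoxon_rank_sum(x, y) -> tuple[float, float, str]:
    """Wilcoxon rank-sum (Mann-Whitney) test.

    Uses exact enumeration when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie and
    continuity corrections. Returns ``(U, two_sided_p, method)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    combined = np.concatenate([x, y])
    no_ties = len(np.unique(combined)) == combined.size
    if combined.size <= 20 and no_ties:
        method = "exact"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        method = "normal-approximation"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=True)
    return float(res.statistic), float(res.pvalue), method


CONTINUOUS = "continuous"
CATEGORICAL = "categorical"


def cohort_summary(
    metadata: pd.DataFrame,
    grouping: str = "event",
    variables: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Table-1-style baseline summary split by a binary grouping column.

    Continuous variables are reported mean +/- SD per group with a Wilcoxon
    rank-sum p; categorical variables as within-group percentages per level
    with a Fisher exact p. Constant variables are reported with p = 1 and a
    degenerate-variable note.
    """
    if variables is None:
        variables = {
            "age": CONTINUOUS, "bmi": CONTINUOUS,
            "sex": CATEGORICAL, "stage": CATEGORICAL,
            "met_sites": CATEGORICAL, "antibiotics": CATEGORICAL,
        }
    g = metadata[grouping]
    levels = sorted(g.unique())
    if len(levels) != 2:
        raise ValueError("grouping must be binary")
    rows = []
    for var, kind in variables.items():
        col = metadata[var]
        note = ""
        if col.nunique() <= 1:
            p = 1.0
            note = "degenerate: variable is constant"
            if kind == CONTINUOUS:
                summ = {lvl: f"{col[g == lvl].mean():.1f} ± {col[g == lvl].std():.1f}"
                        for lvl in levels}
                rows.append({"variable": var, "level": "", **{f"group_{lvl}": summ[lvl]
                            for lvl in levels}, "p": p, "test": "none", "note": note})
            else:
                for cat in sorted(col.astype(str).unique()):
                    pct = {lvl: 100.0 * (col[g == lvl].astype(str) == cat).mean()
                           for lvl in levels}
                    rows.append({"variable": var, "level": cat,
                                 **{f"group_{lvl}": f"{pct[lvl]:.1f}%" for lvl in levels},
                                 "p": p, "test": "none", "note": note})
            continue
        if kind == CONTINUOUS:
            xs = [col[g == lvl].to_numpy(dtype=float) for lvl in levels]
            _, p, method = wilcoxon_rank_sum(xs[0], xs[1])
            rows.append({"variable": var, "level": "",
                         **{f"group_{lvl}": f"{x.mean():.1f} ± {x.std(ddof=1):.1f}"
                            for lvl, x in zip(levels, xs)},
                         "p": p, "test": f"wilcoxon ({method})", "note": note})
        else:
            cats = sorted(col.astype(str).unique())
            tab = np.array([[int(((g == lvl) & (col.astype(str) == cat)).sum())
                             for cat in cats] for lvl in levels])
            p = fisher_exact(tab)
            for cat in cats:
                pct = {lvl: 100.0 * (col[g == lvl].astype(str) == cat).mean()
                       for lvl in levels}
                rows.append({"variable": var, "level": cat,
                             **{f"group_{lvl}": f"{pct[lvl]:.1f}%" for lvl in levels},
                             "p": p, "test": "fisher", "note": note})
    return pd.DataFrame(rows)
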