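"""Statistical comparison and multi-criteria ranking of segmentation methods.

One-way ANOVA with Tukey's HSD post-hoc test, paired Wilcoxon
signed-rank tests with Bonferroni-adjusted significance levels, and
TOPSIS (Technique for Order of Preference by Similarity to Ideal
Solution) ranking over a methods-by-criteria decision matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass(frozen=True)
class AnovaTable:
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    df_total: int
    ms_between: float
    ms_within: float
    f_stat: float
    p_value: float
    f_crit: float


def one_way_anova(groups: list[np.ndarray], alpha: float = 0.05) -> AnovaTable:
    """Standard fixed-effects one-way ANOVA decomposition.

    `groups` is a list of >= 2 samples of >= 2 values each.  The p-value
    comes from the F(df_between, df_within) distribution; f_crit is its
    upper-alpha quantile.  If every observation is identical the test is
    degenerate and F is reported as 0 with a warning.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    all_vals = np.concatenate(groups)
    grand = all_vals.mean()
    n_total = all_vals.size
    k = len(groups)
    ss_between = float(sum(g.size * (g.mean() - grand) ** 2 for g in groups))
    ss_within = float(sum(((g - g.mean()) ** 2).sum() for g in groups))
    ss_total = float(((all_vals - grand) ** 2).sum())
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        warnings.warn("zero within-group variance: degenerate ANOVA, F set to 0")
        f_stat, p_value = 0.0, 1.0
    else:
        f_stat = ms_between / ms_within
        p_value = float(sps.f.sf(f_stat, df_between, df_within))
    f_crit = float(sps.f.ppf(1.0 - alpha, df_between, df_within))
    return AnovaTable(ss_between=ss_between, ss_within=ss_within,
                      ss_total=ss_total, df_between=df_between,
                      df_within=df_within, df_total=n_total - 1,
                      ms_between=ms_between, ms_within=ms_within,
                      f_stat=f_stat, p_value=p_value, f_crit=f_crit)


def tukey_hsd(groups: list[np.ndarray], alpha: float = 0.05,
              names: list[str] | None = None) -> pd.DataFrame:
    """Tukey honestly-significant-difference test for balanced groups.

    For each pair the studentized-range statistic
    ``q = |mean_i - mean_j| / sqrt(MS_within / n)`` is compared with the
    upper-alpha quantile of the studentized range with (k, df_within)
    parameters.  Returns one row per pair: q, q_crit, significant.
    """
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    sizes = {g.size for g in groups}
    if len(sizes) != 1:
        raise ValueError("Tukey HSD here requires balanced groups")
    n = sizes.pop()
    table = one_way_anova(groups, alpha=alpha)
    k = len(groups)
    q_crit = float(sps.studentized_range.ppf(1.0 - alpha, k, table.df_within))
    se = np.sqrt(table.ms_within / n)
    names = names or [f"group{i}" for i in range(k)]
    rows = []
    for i, j in combinations(range(k), 2):
        diff = abs(groups[i].mean() - groups[j].mean())
        q = diff / se if se > 0 else 0.0
        rows.append({"pair": f"{names[i]} vs {names[j]}", "q": q,
                     "q_crit": q_crit, "significant": bool(q > q_crit)})
    return pd.DataFrame(rows)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired Wilcoxon signed-rank p-value.

    Zero differences are dropped (Wilcoxon convention) and ties
    mid-ranked.  Exact null distribution for n <= 25 without ties,
    normal approximation with continuity correction otherwise.  All
    differences zero gives p = 1 with a warning.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("all paired differences are zero; p = 1")
        return 1.0
    has_ties = np.unique(np.abs(d)).size < d.size
    method = "exact" if (d.size <= 25 and not has_ties) else "approx"
    res = sps.wilcoxon(d, zero_method="wilcox", alternative="two-sided",
                       correction=(method == "approx"), method=method)
    return float(res.pvalue)


def bonferroni(alpha: float, k: int) -> float:
    """Adjusted per-comparison significance level alpha / k."""
    if k < 1:
        raise ValueError("number of comparisons must be >= 1")
    return alpha / k


@dataclass
class DecisionMatrix:
    """Methods-by-criteria table for TOPSIS.

    is_benefit flags criteria where larger is better (False = cost,
    e.g. the false-positive rate).  Weights default to equal and are
    normalized to sum 1.
    """

    values: pd.DataFrame                 # rows: alternatives, cols: criteria
    is_benefit: dict[str, bool]
    weights: dict[str, float] | None = None

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        if set(self.is_benefit) != set(cols):
            raise ValueError("is_benefit must flag every criterion")
        if self.weights is None:
            self.weights = {c: 1.0 / len(cols) for c in cols}
        total = sum(self.weights.values())
        if total <= 0 or any(w < 0 for w in self.weights.values()):
            raise ValueError("weights must be non-negative with positive sum")
        self.weights = {c: w / total for c, w in self.weights.items()}


def topsis(dm: DecisionMatrix) -> pd.DataFrame:
    """TOPSIS ranking: closeness to the ideal, distance from the anti-ideal.

    Columns are vector-normalized (root-sum-square) and weighted; the
    ideal takes the best value per criterion (max for benefit, min for
    cost) and the anti-ideal the worst.  Alternatives are ranked by
    descending closeness coefficient ``C = d- / (d+ + d-)``; ties share
    the better rank in stable (input) order.
    """
    vals = dm.values.to_numpy(dtype=np.float64)
    norms = np.sqrt((vals ** 2).sum(axis=0))
    if np.any(norms == 0):
        raise ValueError("a criterion column is all zero; cannot normalize")
    w = np.array([dm.weights[c] for c in dm.values.columns])
    v = vals / norms * w
    benefit = np.array([dm.is_benefit[c] for c in dm.values.columns])
    ideal = np.where(benefit, v.max(axis=0), v.min(axis=0))
    anti = np.where(benefit, v.min(axis=0), v.max(axis=0))
    d_pos = np.sqrt(((v - ideal) ** 2).sum(axis=1))
    d_neg = np.sqrt(((v - anti) ** 2).sum(axis=1))
    closeness = d_neg / (d_pos + d_neg)

    order = np.argsort(-closeness, kind="stable")
    ranks = np.empty(len(closeness), dtype=np.int64)
    prev_c, prev_rank = None, 0
    for pos, idx in enumerate(order, start=1):
        if prev_c is not None and closeness[idx] == prev_c:
            ranks[idx] = prev_rank   # ties share the better rank
        else:
            ranks[idx] = pos
            prev_c, prev_rank = closeness[idx], pos
    return pd.DataFrame({"closeness": closeness, "rank": ranks},
                        index=dm.values.index).sort_values("rank")
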