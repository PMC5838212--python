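"""One-way ANOVA with Tukey post hoc comparisons for per-unit summaries.

Used for per-neuron morphometrics (dendritic length, surface area, node /
end / dendrite counts, complexity index) and any other long-format
(unit, group, value) table.  The ANOVA returns the full sums-of-squares
decomposition; Tukey's HSD uses the studentized-range distribution with the
Tukey-Kramer harmonic-mean standard error, so unbalanced designs (e.g.
15-20 neurons per group) are handled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["AnovaResult", "one_way_anova", "tukey_hsd"]


@dataclass
class AnovaResult:
    f: float
    p: float
    df_between: int
    df_within: int
    ss_between: float
    ss_within: float
    ss_total: float
    degenerate: bool = False  # all groups constant: F is 0/0


def _groups(g: pd.DataFrame, group_col: str, value_col: str) -> dict[str, np.ndarray]:
    out = {
        str(name): sub[value_col].to_numpy(float)
        for name, sub in g.groupby(group_col, sort=False)
    }
    if len(out) < 2:
        raise ValueError("need at least 2 groups")
    for name, vals in out.items():
        if vals.size < 2:
            raise ValueError(f"group {name!r} has fewer than 2 units")
    return out


def one_way_anova(
    g: pd.DataFrame, group_col: str = "group", value_col: str = "value"
) -> AnovaResult:
    """Standard one-way fixed-effects ANOVA from the SS decomposition.

    SS_total = SS_between + SS_within; F = MS_between / MS_within with
    (k-1, N-k) degrees of freedom, two-sided p from the F distribution.
    """
    groups = _groups(g, group_col, value_col)
    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    ss_between = sum(v.size * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    ss_total = ((all_vals - grand) ** 2).sum()
    df_b = len(groups) - 1
    df_w = all_vals.size - len(groups)
    if ss_within == 0:
        if ss_between == 0:
            # every observation identical: F = 0/0, flagged rather than raised
            return AnovaResult(np.nan, np.nan, df_b, df_w, 0.0, 0.0, 0.0, degenerate=True)
        return AnovaResult(np.inf, 0.0, df_b, df_w, float(ss_between), 0.0,
                           float(ss_total), degenerate=True)
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return AnovaResult(float(f), p, df_b, df_w, float(ss_between), float(ss_within),
                       float(ss_total))


def tukey_hsd(
    g: pd.DataFrame,
    alpha: float = 0.05,
    group_col: str = "group",
    value_col: str = "value",
) -> pd.DataFrame:
    """Tukey's honestly-significant-difference pairwise comparisons.

    For each pair (i, j): q = |mean_i - mean_j| / sqrt(MSW/2 * (1/n_i + 1/n_j))
    (Tukey-Kramer for unbalanced groups); the adjusted p is the survival
    function of the studentized range with k groups and N-k df.  Returns a
    tidy frame (group1, group2, diff, se, q, p_adj, reject).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    groups = _groups(g, group_col, value_col)
    anova = one_way_anova(g, group_col, value_col)
    k = len(groups)
    msw = anova.ss_within / anova.df_within
    names = list(groups)
    rows = []
    for a in range(k):
        for b in range(a + 1, k):
            va, vb = groups[names[a]], groups[names[b]]
            diff = vb.mean() - va.mean()
            se = np.sqrt(msw / 2.0 * (1.0 / va.size + 1.0 / vb.size))
            if se == 0:
                q = np.inf if diff != 0 else 0.0
                p_adj = 0.0 if diff != 0 else 1.0
            else:
                q = abs(diff) / se
                p_adj = float(stats.studentized_range.sf(q, k, anova.df_within))
            rows.append(
                {
                    "group1": names[a],
                    "group2": names[b],
                    "diff": float(diff),
                    "se": float(se),
                    "q": float(q),
                    "p_adj": min(max(p_adj, 0.0), 1.0),
                    "reject": bool(p_adj < alpha),
                }
            )
    return pd.DataFrame(rows)
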