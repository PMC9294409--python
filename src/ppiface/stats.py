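"""Group-comparison statistics over descriptor tables.

One-way ANOVA compares a descriptor's distribution across interface
classes; where it indicates differences, Tukey's Honestly Significant
Difference resolves which pairs of classes differ (Tukey–Kramer for
unbalanced designs).  Pearson's r is used for descriptor–descriptor
association, and 2D Gaussian-KDE summaries back the density plots.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps


class StatsInputError(ValueError):
    pass


@dataclass
class AnovaResult:
    f_stat: float
    df_between: int
    df_within: int
    p_value: float


@dataclass
class TukeyResult:
    table: List[Tuple]     # (group_i, group_j, mean_diff, q_stat, adjusted_p, reject)
    alpha: float


def _check_groups(groups: Sequence[Sequence[float]]):
    if len(groups) < 2:
        raise StatsInputError("need at least two groups")
    arrs = [np.asarray(g, float) for g in groups]
    for i, g in enumerate(arrs):
        if len(g) < 2:
            raise StatsInputError(f"group {i} has n < 2: variance undefined")
    return arrs


def one_way_anova(groups: Sequence[Sequence[float]]) -> AnovaResult:
    """Classical F = MS_between / MS_within with p from the F distribution."""
    arrs = _check_groups(groups)
    f, p = sps.f_oneway(*arrs)
    k = len(arrs)
    n = sum(len(g) for g in arrs)
    # identical groups: zero between-group variance gives F = 0, p = 1
    if np.isnan(f):
        f, p = 0.0, 1.0
    return AnovaResult(f_stat=float(f), df_between=k - 1, df_within=n - k,
                       p_value=float(p))


def tukey_hsd(groups: Sequence[Sequence[float]],
              labels: Optional[Sequence] = None,
              alpha: float = 0.05) -> TukeyResult:
    """Studentized-range pairwise comparisons with pooled within-group MS.

    q = |mean_i − mean_j| / sqrt(MSW/2 · (1/n_i + 1/n_j)) — the Tukey–Kramer
    form, exact for balanced designs.  Adjusted p comes from the studentized
    range distribution with k groups and N−k degrees of freedom.
    """
    arrs = _check_groups(groups)
    k = len(arrs)
    labels = list(labels) if labels is not None else list(range(k))
    n_total = sum(len(g) for g in arrs)
    df_w = n_total - k
    msw = sum(((g - g.mean()) ** 2).sum() for g in arrs) / df_w
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(arrs[j].mean() - arrs[i].mean())
            se = np.sqrt(msw / 2.0 * (1.0 / len(arrs[i]) + 1.0 / len(arrs[j])))
            if se == 0:
                q = 0.0 if diff == 0 else np.inf
            else:
                q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_w)) if np.isfinite(q) else 0.0
            p = min(max(p, 0.0), 1.0)
            rows.append((labels[i], labels[j], diff, float(q), p, p < alpha))
    return TukeyResult(table=rows, alpha=alpha)


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires n ≥ 3 and nonzero variances."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise StatsInputError("need matched samples with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise StatsInputError("undefined correlation: zero variance")
    r, _ = sps.pearsonr(x, y)
    return float(r)


def kde2d_summary(x: Sequence[float], y: Sequence[float],
                  gridsize: int = 50) -> pd.DataFrame:
    """Gridded 2D Gaussian KDE (Scott bandwidth) as a tidy DataFrame with
    columns x, y, density."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    kde = sps.gaussian_kde(np.vstack([x, y]))
    xs = np.linspace(x.min(), x.max(), gridsize)
    ys = np.linspace(y.min(), y.max(), gridsize)
    gx, gy = np.meshgrid(xs, ys)
    dens = kde(np.vstack([gx.ravel(), gy.ravel()]))
    return pd.DataFrame({"x": gx.ravel(), "y": gy.ravel(), "density": dens})


@dataclass
class DatasetSummary:
    value_column: str
    group_column: str
    group_means: Dict[str, float]
    group_counts: Dict[str, int]
    anova: AnovaResult
    tukey: Optional[TukeyResult]


def compare_descriptor(table: pd.DataFrame, value: str, group: str,
                       alpha: float = 0.05) -> DatasetSummary:
    """Compare one descriptor column across interface classes."""
    sub = table[[value, group]].dropna()
    grouped = {str(g): np.asarray(v[value], float)
               for g, v in sub.groupby(group) if len(v) >= 2}
    if len(grouped) < 2:
        raise StatsInputError("need >= 2 groups with n >= 2 after dropping NaN")
    names = sorted(grouped)
    groups = [grouped[n] for n in names]
    anova = one_way_anova(groups)
    tukey = tukey_hsd(groups, labels=names, alpha=alpha)
    return DatasetSummary(value_column=value, group_column=group,
                          group_means={n: float(g.mean()) for n, g in zip(names, groups)},
                          group_counts={n: int(len(g)) for n, g in zip(names, groups)},
                          anova=anova, tukey=tukey)
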