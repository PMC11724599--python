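"""Rank-based group comparisons: tie-corrected Kruskal–Wallis and Dunn post hoc.

The Kruskal–Wallis statistic over k groups of pooled size N, with midranks
R and tie groups of sizes t, is

    H = [ 12/(N(N+1)) * sum_i R_i^2/n_i  -  3(N+1) ] / C,
    C = 1 - sum_t (t^3 - t) / (N^3 - N),

compared against the chi-square distribution with k-1 degrees of freedom
(the standard large-sample reference, used at all N).  When every pooled
value is tied C vanishes; that degenerate input returns H = 0 by convention.

Dunn's post-hoc z for groups i, j uses mean ranks and the tie-corrected
variance

    z_ij = (Rbar_i - Rbar_j) /
           sqrt[ (N(N+1)/12 - sum_t (t^3 - t)/(12(N-1))) (1/n_i + 1/n_j) ],

with two-sided normal p-values and a Bonferroni multiplier of k(k-1)/2.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError


def midranks(values) -> np.ndarray:
    """Midranks of a 1-d sample: ties share the mean of their rank span."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("midranks needs at least one value")
    if not np.isfinite(x).all():
        raise ValidationError("midranks requires finite values")
    return sps.rankdata(x, method="average")


@dataclass
class KWResult:
    H: float
    df: int
    p_value: float
    group_sizes: tuple[int, ...]


@dataclass
class DunnPair:
    group_i: object
    group_j: object
    z: float
    p_raw: float
    p_adjusted: float


def _tie_term(pooled_ranks: np.ndarray) -> float:
    _, counts = np.unique(pooled_ranks, return_counts=True)
    t = counts.astype(float)
    return float(np.sum(t**3 - t))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> KWResult:
    """Tie-corrected Kruskal–Wallis rank-sum test over k >= 2 groups."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("every group must be non-empty")
    sizes = tuple(int(a.size) for a in arrays)
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    if n_total < 3:
        raise ValidationError("need a pooled sample of at least 3 values")
    ranks = midranks(pooled)
    tie = _tie_term(ranks)
    correction = 1.0 - tie / (n_total**3 - n_total)
    k = len(arrays)
    if correction <= 0.0:
        # every pooled value identical: no evidence against the null
        return KWResult(H=0.0, df=k - 1, p_value=1.0, group_sizes=sizes)
    bounds = np.cumsum([0] + list(sizes))
    rank_sums = [ranks[bounds[i]:bounds[i + 1]].sum() for i in range(k)]
    h_raw = (12.0 / (n_total * (n_total + 1))
             * sum(rs**2 / n for rs, n in zip(rank_sums, sizes))
             - 3.0 * (n_total + 1))
    h = h_raw / correction
    h = max(h, 0.0)
    p = float(sps.chi2.sf(h, k - 1))
    return KWResult(H=float(h), df=k - 1, p_value=p, group_sizes=sizes)


def dunn_bonferroni(groups: Sequence[Sequence[float]],
                    labels: Optional[Sequence] = None) -> list[DunnPair]:
    """Dunn's pairwise post-hoc comparisons with Bonferroni adjustment."""
    if len(groups) < 2:
        raise ValidationError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValidationError("every group must be non-empty")
    if labels is None:
        labels = list(range(len(arrays)))
    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = midranks(pooled)
    tie = _tie_term(ranks)
    bounds = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean()
                  for i in range(len(arrays))]
    k = len(arrays)
    n_pairs = k * (k - 1) // 2
    var_base = (n_total * (n_total + 1) / 12.0
                - tie / (12.0 * (n_total - 1)))
    out = []
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(var_base * (1.0 / arrays[i].size + 1.0 / arrays[j].size))
        z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
        p_raw = float(2.0 * sps.norm.sf(abs(z)))
        out.append(DunnPair(group_i=labels[i], group_j=labels[j], z=float(z),
                            p_raw=p_raw,
                            p_adjusted=min(1.0, p_raw * n_pairs)))
    return out


def compare_groups(table: pd.DataFrame, value_col: str, group_col: str, *,
                   alpha: float = 0.05,
                   exclude_years: Optional[Sequence[int]] = None,
                   year_col: str = "year") -> dict:
    """KW comparison of one metric across groups, Dunn attached when due.

    Dunn post-hoc runs only when the KW test is significant at ``alpha`` and
    there are more than two groups.  Years listed in ``exclude_years`` are
    dropped before testing (they remain in data summaries elsewhere).
    """
    df = table.dropna(subset=[value_col])
    if exclude_years and year_col in df.columns:
        df = df[~df[year_col].isin(list(exclude_years))]
    labels = sorted(df[group_col].dropna().unique().tolist())
    groups = [df.loc[df[group_col] == lab, value_col].to_numpy()
              for lab in labels]
    groups = [g for g in groups if g.size > 0]
    labels = [lab for lab, g in zip(labels, groups) if g.size > 0]
    if len(groups) < 2:
        raise ValidationError(
            f"need >= 2 non-empty groups of {value_col!r} by {group_col!r}")
    kw = kruskal_wallis(groups)
    result = {"metric": value_col, "grouping": group_col, "groups": labels,
              "H": kw.H, "df": kw.df, "p_value": kw.p_value,
              "group_sizes": kw.group_sizes, "dunn": None}
    if kw.p_value < alpha and len(groups) > 2:
        result["dunn"] = dunn_bonferroni(groups, labels)
    return result


def compare_species(table: pd.DataFrame, metric: str, *,
                    grouping: str = "species", alpha: float = 0.05,
                    exclude_years: Optional[Sequence[int]] = None) -> dict:
    """Species (or year-within-species) comparison of a residency/space-use
    metric, mirroring the in-text reporting shape (H, df, p, pairs)."""
    allowed = {"ri", "ri_stat", "n_stations", "raw_area_km2",
               "clipped_area_km2", "arrival_doy", "departure_doy",
               "duration_days", "n_detection_days"}
    if metric not in allowed:
        raise ValidationError(f"unknown metric {metric!r}; one of {sorted(allowed)}")
    return compare_groups(table, metric, grouping, alpha=alpha,
                          exclude_years=exclude_years)
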