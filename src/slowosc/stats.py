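"""Group comparisons and mean ± SEM summaries.

The comparison path mirrors common practice in in-vivo imaging studies:
each group is screened for normality (Shapiro–Wilk), after which all-normal
data go to a t test (2 groups) or one-way ANOVA (3+), and non-normal data to
Mann–Whitney (2 groups) or Kruskal–Wallis followed by Dunn's multiple
comparison test (3+).  The significance level is 0.05 for two conditions and
0.025 for three or more.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as ss

__all__ = ["GroupComparison", "choose_and_run_test", "summarize", "dunn_posthoc"]

#: Significance level by number of conditions compared.
ALPHA_TWO_GROUPS = 0.05
ALPHA_THREE_PLUS = 0.025


@dataclass
class GroupComparison:
    """Outcome of an automatically selected group comparison."""

    group_labels: list[str]
    test_used: str
    statistic: float
    p_value: float
    alpha_used: float
    significant: bool
    normality_p: dict[str, float]
    posthoc: pd.DataFrame | None = None


def _alpha_for(k: int) -> float:
    return ALPHA_TWO_GROUPS if k == 2 else ALPHA_THREE_PLUS


def dunn_posthoc(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Dunn's multiple-comparison test after Kruskal–Wallis.

    Rank-based pairwise z statistics with tie correction; two-sided p-values
    are Bonferroni-adjusted over all pairs.
    """
    labels = list(groups)
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(data)
    n_total = pooled.size
    ranks = ss.rankdata(pooled)
    # tie correction term: sum(t^3 - t) over tie groups
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term / (12.0 * (n_total - 1))

    mean_ranks = {}
    start = 0
    for g, arr in zip(labels, data):
        mean_ranks[g] = ranks[start : start + arr.size].mean()
        start += arr.size

    m = len(labels) * (len(labels) - 1) // 2
    rows = []
    for a, b in itertools.combinations(labels, 2):
        na, nb = len(groups[a]), len(groups[b])
        se = np.sqrt(var_factor * (1.0 / na + 1.0 / nb))
        z = (mean_ranks[a] - mean_ranks[b]) / se
        p = 2.0 * ss.norm.sf(abs(z))
        rows.append({"group_a": a, "group_b": b, "z": z, "p_value": min(1.0, p * m)})
    return pd.DataFrame(rows)


def choose_and_run_test(
    groups: Mapping[str, Sequence[float]],
    normality_alpha: float = 0.05,
) -> GroupComparison:
    """Screen for normality, select the appropriate test, and apply the alpha rule.

    Requires at least two groups with n >= 3 each.  Returns the test name,
    the p-value, and a significance flag at alpha 0.05 (two conditions) or
    0.025 (three or more).
    """
    labels = list(groups)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    data = [np.asarray(groups[g], dtype=float) for g in labels]
    for g, arr in zip(labels, data):
        if arr.size < 3:
            raise ValueError(f"group {g!r} has n={arr.size} < 3")

    normality_p = {}
    all_normal = True
    for g, arr in zip(labels, data):
        if np.ptp(arr) == 0:
            # constant sample: Shapiro is undefined; treat as non-normal
            normality_p[g] = 0.0
            all_normal = False
            continue
        p = float(ss.shapiro(arr).pvalue)
        normality_p[g] = p
        if p < normality_alpha:
            all_normal = False

    posthoc = None
    if len(labels) == 2:
        if all_normal:
            res = ss.ttest_ind(data[0], data[1])
            test_used = "t"
        else:
            res = ss.mannwhitneyu(data[0], data[1], alternative="two-sided")
            test_used = "Mann-Whitney"
    else:
        if all_normal:
            res = ss.f_oneway(*data)
            test_used = "ANOVA"
        else:
            res = ss.kruskal(*data)
            test_used = "Kruskal-Wallis+Dunn"
            posthoc = dunn_posthoc(groups)

    stat = float(res.statistic)
    p_value = float(res.pvalue)
    if np.isnan(p_value):
        # identical constant groups: no evidence of a difference
        p_value = 1.0
    alpha = _alpha_for(len(labels))
    return GroupComparison(
        group_labels=labels,
        test_used=test_used,
        statistic=stat,
        p_value=p_value,
        alpha_used=alpha,
        significant=bool(p_value < alpha),
        normality_p=normality_p,
        posthoc=posthoc,
    )


def summarize(groups: Mapping[str, Sequence[float]]) -> pd.DataFrame:
    """Mean ± SEM table, one row per group (SEM = sample SD / sqrt(n)).

    A single-value group gets SEM = NaN (flagged, not zero).
    """
    if not groups:
        raise ValueError("no groups to summarize")
    rows = []
    for g, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        if arr.size == 0:
            raise ValueError(f"group {g!r} is empty")
        sem = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else float("nan")
        rows.append({"group": g, "n": arr.size, "mean": float(arr.mean()), "sem": sem})
    return pd.DataFrame(rows)
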