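"""Two-group and multi-group hypothesis tests used across the analysis.

Welch's unequal-variance t test is the default two-group comparison (the
classical pooled test is available behind a flag); one-way ANOVA serves the
substitution-class comparisons of effect scores; and a one-way MANOVA
(Pillai trace with the standard F approximation) tests the population effect
on deleterious allele frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WelchResult", "AnovaResult", "ManovaResult",
           "welch_t_test", "one_way_anova", "population_effect_manova"]


@dataclass
class WelchResult:
    t: float
    df: float
    p: float
    mean_x: float
    mean_y: float


@dataclass
class AnovaResult:
    F: float
    df1: int
    df2: int
    p: float


@dataclass
class ManovaResult:
    pillai: float
    F: float
    df_effect: int
    df_error: int
    df1: float
    df2: float
    p: float


def welch_t_test(x: Sequence[float], y: Sequence[float],
                 equal_var: bool = False) -> WelchResult:
    """Two-sided t test of mean(x) - mean(y); Welch by default."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least two values")
    if np.var(x) == 0 and np.var(y) == 0:
        raise ValueError("zero variance in both groups")
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue),
                       float(x.mean()), float(y.mean()))


def one_way_anova(values: Sequence[float], groups: Sequence) -> AnovaResult:
    """Classical one-way fixed-effects ANOVA from a long (value, group) layout.

    Groups with a single member are retained: they contribute to the
    between-group sum of squares but no within-group degrees of freedom.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    if values.shape[0] != groups.shape[0]:
        raise ValueError("values and groups must align")
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    n = values.size
    if k < 2:
        raise ValueError("need at least two groups")
    if n - k < 1:
        raise ValueError("no residual degrees of freedom")
    grand = values.mean()
    ss_between = 0.0
    ss_within = 0.0
    for g in range(k):
        v = values[inverse == g]
        if v.size == 0:
            raise ValueError("empty group")
        ss_between += v.size * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df1, df2 = k - 1, n - k
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else np.inf
    else:
        F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return AnovaResult(float(F), df1, df2, p)


def population_effect_manova(responses, groups) -> ManovaResult:
    """One-way MANOVA: Pillai's trace of the group effect on a (possibly
    univariate) response matrix, with the usual F approximation.

    ``responses`` is (n_obs, n_responses) — observations are loci replicated
    across populations in the long layout — and ``groups`` the population
    label per observation.  With a single response column this reduces
    exactly to the one-way ANOVA F.
    """
    Y = np.asarray(responses, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    groups = np.asarray(groups, dtype=object)
    n, p = Y.shape
    labels, inverse = np.unique(groups, return_inverse=True)
    k = labels.size
    if k < 2:
        raise ValueError("need at least two groups")
    if n <= k + p - 1:
        raise ValueError("too few observations for the number of groups/responses")
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    E = np.zeros((p, p))
    for g in range(k):
        Yg = Y[inverse == g]
        dg = Yg.mean(axis=0) - grand
        H += Yg.shape[0] * np.outer(dg, dg)
        R = Yg - Yg.mean(axis=0)
        E += R.T @ R
    df_h, df_e = k - 1, n - k
    # Pillai V = tr(H (H+E)^-1), F approximation with s, m, n parameters
    V = float(np.trace(H @ np.linalg.pinv(H + E)))
    s = min(p, df_h)
    m = (abs(p - df_h) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    if V >= s:  # complete separation
        F = np.inf
        pval = 0.0
    else:
        F = (df2 / df1) * (V / (s - V))
        pval = float(stats.f.sf(F, df1, df2))
    return ManovaResult(V, float(F), df_h, df_e, float(df1), float(df2), pval)
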