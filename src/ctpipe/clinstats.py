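"""Clinical statistics: group comparisons from summary data and
functional-connectivity / symptom-severity regression with BH-FDR.

``anova_from_summary`` and ``ttest_from_summary`` recompute the classical
one-way ANOVA F and pooled-variance two-sample t from per-group
(n, mean, SD) triples, so that published demographics tables can be
checked without subject-level data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GroupSummary",
    "anova_from_summary",
    "ttest_from_summary",
    "fc_score_regression",
]


@dataclass(frozen=True)
class GroupSummary:
    """Sample size, mean, and SD of one variable in one group."""

    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise ValueError("group summary requires n >= 2")
        if self.sd < 0:
            raise ValueError("SD must be nonnegative")


def anova_from_summary(groups):
    """One-way ANOVA from per-group summaries.

    Between-group sum of squares uses the grand mean weighted by group
    sizes; within-group sum of squares is sum of (n_g - 1) * sd_g^2.

    Returns ``(F, p, (df_between, df_within))``.
    """
    groups = list(groups)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    ns = np.array([g.n for g in groups], float)
    means = np.array([g.mean for g in groups], float)
    sds = np.array([g.sd for g in groups], float)
    grand = (ns * means).sum() / ns.sum()
    ss_between = (ns * (means - grand) ** 2).sum()
    ss_within = ((ns - 1) * sds**2).sum()
    df_b = len(groups) - 1
    df_w = int(ns.sum()) - len(groups)
    if ss_within == 0:
        raise ValueError("zero within-group variance")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(f, df_b, df_w)
    return float(f), float(p), (df_b, df_w)


def ttest_from_summary(a: GroupSummary, b: GroupSummary):
    """Pooled-variance two-sample t from summaries, direction b - a.

    Returns ``(t, p, df)`` with df = n_a + n_b - 2.
    """
    df = a.n + b.n - 2
    sp2 = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if sp2 == 0:
        if a.mean == b.mean:
            return 0.0, 1.0, df
        raise ValueError("zero pooled variance with unequal means")
    t = (b.mean - a.mean) / np.sqrt(sp2 * (1 / a.n + 1 / b.n))
    p = 2 * stats.t.sf(abs(t), df)
    return float(t), float(p), df


def fc_score_regression(
    features: pd.DataFrame,
    scores: pd.DataFrame,
    score_name: str,
    feature_columns=None,
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Per-feature OLS of a clinical score on connectivity, with BH-FDR.

    ``features`` and ``scores`` are joined on ``subject_id``.  For every
    feature the score is regressed on the feature value (slope, intercept,
    Pearson r, two-sided p); Benjamini-Hochberg q-values are computed
    across all non-degenerate features of the run.  Constant features are
    flagged (``constant=True``) and excluded from the FDR family.
    """
    merged = features.merge(scores[["subject_id", score_name]], on="subject_id")
    if len(merged) < 3:
        raise ValueError("need at least 3 complete subject rows")
    if len(merged) < len(features):
        raise ValueError("subject ids in features and scores do not match")
    if feature_columns is None:
        feature_columns = [
            c for c in features.columns if c not in ("subject_id", "group")
        ]
    y = merged[score_name].to_numpy(float)
    rows = []
    for col in feature_columns:
        x = merged[col].to_numpy(float)
        if np.ptp(x) == 0:
            rows.append(
                dict(feature=col, slope=np.nan, intercept=np.nan, r=np.nan,
                     p=np.nan, constant=True)
            )
            continue
        res = stats.linregress(x, y)
        rows.append(
            dict(feature=col, slope=res.slope, intercept=res.intercept,
                 r=res.rvalue, p=res.pvalue, constant=False)
        )
    out = pd.DataFrame(rows)
    out["q"] = np.nan
    ok = ~out["constant"]
    if ok.any():
        out.loc[ok, "q"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < fdr_q
    return out
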