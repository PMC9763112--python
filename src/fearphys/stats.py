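"""Assumption-gated group statistics and behavioral summary formulas.

The gate follows the conventional decision tree: Shapiro-Wilk normality per
group (optionally retried after a natural-log transform when requested),
Levene homogeneity of variance, then an unpaired two-sided t-test when both
hold, otherwise a Mann-Whitney U test. The full decision trail is recorded
on the returned :class:`~fearphys.core.GroupComparison`.

The repeated-measures ANOVA is the mixed design (one between-subjects group
factor, one within-subjects time factor, balanced and complete), with the
standard sums-of-squares partition and no sphericity correction by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import GroupComparison, ValidationError

__all__ = [
    "SessionFreezing",
    "block1_mean",
    "recognition_index",
    "percent_open_arm",
    "mann_whitney",
    "gated_two_group_test",
    "one_way_anova",
    "two_way_rm_anova",
]

ALPHA = 0.05


@dataclass
class SessionFreezing:
    """Per-tone freezing percentages for one fear-test session (6 tones)."""

    group: str
    subject: str
    day: int
    per_tone_freezing: list = field(default_factory=list)

    def __post_init__(self):
        v = np.asarray(self.per_tone_freezing, dtype=np.float64)
        if np.any(v < 0) or np.any(v > 100):
            raise ValidationError("freezing values must be percentages in [0, 100]")
        self.per_tone_freezing = list(v)


def block1_mean(session: SessionFreezing) -> float:
    """Block-1 freezing: mean of tones 1 and 2 of the session."""
    if len(session.per_tone_freezing) < 2:
        raise ValidationError("block-1 mean requires tones 1 and 2")
    return float(np.mean(session.per_tone_freezing[:2]))


def recognition_index(t_novel: float, t_familiar: float) -> float:
    """Novel-object recognition index: novel / (novel + familiar); 0.5 = no preference."""
    if t_novel < 0 or t_familiar < 0:
        raise ValidationError("exploration times must be non-negative")
    total = t_novel + t_familiar
    if total <= 0:
        raise ValidationError("total exploration time must be > 0")
    return t_novel / total


def percent_open_arm(t_open: float, t_closed: float) -> float:
    """Elevated-plus-maze open-arm time: open / (open + closed) * 100."""
    if t_open < 0 or t_closed < 0:
        raise ValidationError("arm times must be non-negative")
    total = t_open + t_closed
    if total <= 0:
        raise ValidationError("total arm time must be > 0")
    return 100.0 * t_open / total


def mann_whitney(x, y) -> GroupComparison:
    """Two-sided Mann-Whitney U test.

    Uses the exact null distribution when n1 + n2 <= 12 and there are no
    ties, otherwise the normal approximation with tie and continuity
    corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(x) + len(y) <= 12 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return GroupComparison(
        test_name="mann-whitney",
        statistic=float(res.statistic),
        df=None,
        p_value=float(res.pvalue),
        detail={"method": method, "n": (len(x), len(y))},
    )


def gated_two_group_test(x, y, log_gate: bool = False) -> GroupComparison:
    """Assumption-gated two-group comparison (two-sided, alpha = 0.05).

    Shapiro-Wilk per group; if normality is rejected and ``log_gate`` is
    set, both groups are natural-log transformed (values must be positive)
    and normality is retested. Levene's test is run on the (possibly
    transformed) data. When normality and homogeneity both hold, an
    unpaired Student t-test is applied; otherwise Mann-Whitney.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if len(x) < 3 or len(y) < 3:
        raise ValidationError("need n >= 3 per group")

    transform = "none"
    sw_x, sw_y = sps.shapiro(x).pvalue, sps.shapiro(y).pvalue
    trail = {"shapiro_raw": (float(sw_x), float(sw_y))}
    normal = sw_x >= ALPHA and sw_y >= ALPHA
    if not normal and log_gate:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValidationError("log transform requires strictly positive values")
        x, y = np.log(x), np.log(y)
        transform = "log"
        sw_x, sw_y = sps.shapiro(x).pvalue, sps.shapiro(y).pvalue
        trail["shapiro_log"] = (float(sw_x), float(sw_y))
        normal = sw_x >= ALPHA and sw_y >= ALPHA

    lev_p = float(sps.levene(x, y).pvalue)
    trail["levene"] = lev_p

    if normal and lev_p >= ALPHA:
        res = sps.ttest_ind(x, y, equal_var=True)
        return GroupComparison(
            test_name="unpaired t-test",
            statistic=float(res.statistic),
            df=len(x) + len(y) - 2,
            p_value=float(res.pvalue),
            transform=transform,
            normality_p=(float(sw_x), float(sw_y)),
            levene_p=lev_p,
            detail=trail,
        )
    mw = mann_whitney(x, y)
    mw.transform = transform
    mw.normality_p = (float(sw_x), float(sw_y))
    mw.levene_p = lev_p
    mw.detail.update(trail)
    return mw


def one_way_anova(groups) -> GroupComparison:
    """One-way between-subjects ANOVA from the sums-of-squares partition."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValidationError("need >= 2 groups with n >= 2 each")
    all_y = np.concatenate(groups)
    grand = all_y.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = len(all_y) - len(groups)
    if ss_within == 0:
        f = 0.0 if ss_between == 0 else np.inf
    else:
        f = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return GroupComparison(
        test_name="one-way ANOVA",
        statistic=float(f),
        df=(df1, df2),
        p_value=p,
        detail={"ss_between": float(ss_between), "ss_within": float(ss_within)},
    )


def two_way_rm_anova(data: pd.DataFrame, dv: str = "value", subject: str = "subject",
                     within: str = "time", between: str = "group") -> pd.DataFrame:
    """Two-way mixed-design ANOVA (between group x within time).

    Requires a balanced complete design: every subject measured exactly once
    at every time level; no imputation. Returns a table with rows for the
    group, time and interaction effects plus the two error strata, columns
    ``effect, ss, df, ms, F, p``. Degrees of freedom are uncorrected
    (no sphericity adjustment).
    """
    df = data[[subject, within, between, dv]].copy()
    if df[dv].isna().any():
        raise ValidationError("missing responses: no imputation is performed")
    times = sorted(df[within].unique())
    subjects = df[subject].unique()
    t = len(times)
    counts = df.groupby([subject, within]).size()
    if (counts != 1).any() or len(df) != len(subjects) * t:
        raise ValidationError("design must be balanced and complete (one value per subject x time)")
    gmap = df.groupby(subject)[between].nunique()
    if (gmap != 1).any():
        raise ValidationError("each subject must belong to exactly one group")

    a = df[between].nunique()
    n_total = len(subjects)
    grand = df[dv].mean()

    subj_means = df.groupby(subject)[dv].mean()
    group_of = df.groupby(subject)[between].first()
    group_means = df.groupby(between)[dv].mean()
    time_means = df.groupby(within)[dv].mean()
    cell_means = df.groupby([between, within])[dv].mean()
    n_per_group = group_of.value_counts()

    ss_total = ((df[dv] - grand) ** 2).sum()
    ss_between_subj = t * ((subj_means - grand) ** 2).sum()
    ss_group = t * sum(n_per_group[g] * (group_means[g] - grand) ** 2 for g in group_means.index)
    ss_subj_err = ss_between_subj - ss_group
    ss_within_subj = ss_total - ss_between_subj
    ss_time = n_total * ((time_means - grand) ** 2).sum()
    ss_inter = sum(
        n_per_group[g] * (cell_means[(g, k)] - group_means[g] - time_means[k] + grand) ** 2
        for g in group_means.index
        for k in times
    )
    ss_err_within = ss_within_subj - ss_time - ss_inter

    df_group, df_subj = a - 1, n_total - a
    df_time = t - 1
    df_inter = (a - 1) * (t - 1)
    df_err_w = (t - 1) * (n_total - a)

    ms_subj = ss_subj_err / df_subj
    ms_err_w = ss_err_within / df_err_w
    rows = []
    for name, ss, d1, ms_err, d2 in (
        (between, ss_group, df_group, ms_subj, df_subj),
        (within, ss_time, df_time, ms_err_w, df_err_w),
        (f"{within} x {between}", ss_inter, df_inter, ms_err_w, df_err_w),
    ):
        ms = ss / d1
        f = ms / ms_err if ms_err > 0 else (0.0 if ms == 0 else np.inf)
        rows.append(dict(effect=name, ss=float(ss), df=d1, ms=float(ms),
                         F=float(f), p=float(sps.f.sf(f, d1, d2)) if np.isfinite(f) else 0.0))
    rows.append(dict(effect=f"subjects within {between} (error)", ss=float(ss_subj_err),
                     df=df_subj, ms=float(ms_subj), F=np.nan, p=np.nan))
    rows.append(dict(effect=f"{within} x subjects (error)", ss=float(ss_err_within),
                     df=df_err_w, ms=float(ms_err_w), F=np.nan, p=np.nan))
    out = pd.DataFrame(rows)
    out.attrs["ss_total"] = float(ss_total)
    return out
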