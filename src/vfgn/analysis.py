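"""Cohort-level statistics for metric tables.

The analysis surface mirrors a classical repeated-measures workflow on a
subjects × trials metric table: one-sample t against a chance constant,
independent two-sample t for group comparisons, a mixed-design (split-plot)
ANOVA with one or two between-subject factors and one within-subject
factor, Pearson age correlations per group, and Holm-corrected pairwise
group tests as the post-hoc surface.

Everything is computed from closed-form sums of squares; scipy supplies
only the reference distributions (t and F tail probabilities).  Sphericity
corrections are not applied (documented limitation); balanced designs are
required for the ANOVA (each subject must have every within-factor level).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TTestResult",
    "AnovaResult",
    "one_sample_t",
    "paired_t",
    "two_sample_t",
    "mixed_anova",
    "age_correlation",
    "pairwise_group_tests",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float
    degenerate: bool = False  # zero-variance input handled by convention

    def __iter__(self):
        return iter((self.t, self.df, self.p))


def one_sample_t(values, mu0: float) -> TTestResult:
    """Classical one-sample t of the mean against ``mu0``, two-sided p.

    Zero variance with mean != mu0 yields p = 0 with a warning flag; zero
    variance with mean == mu0 is undefined and raises.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2 or not np.all(np.isfinite(v)):
        raise ValueError("need >= 2 finite values")
    n = v.size
    m = v.mean()
    s = v.std(ddof=1)
    if s == 0.0:
        if m == mu0:
            raise ValueError("all values equal mu0: t undefined (0/0)")
        warnings.warn("zero variance: t infinite, p set to 0", stacklevel=2)
        return TTestResult(math.inf if m > mu0 else -math.inf, n - 1, 0.0, True)
    t = (m - mu0) / (s / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return TTestResult(t, n - 1, p)


def paired_t(a, b) -> TTestResult:
    """Paired t: the one-sample t of the differences a − b against 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(a - b, 0.0)


def two_sample_t(group_a, group_b, pooled: bool = True) -> TTestResult:
    """Independent two-sample t; pooled variance by default, Welch otherwise."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values")
    na, nb = a.size, b.size
    ma, mb = a.mean(), b.mean()
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if ma == mb:
            raise ValueError("both groups constant and equal: t undefined")
        warnings.warn("zero variance: t infinite, p set to 0", stacklevel=2)
        return TTestResult(math.inf if ma > mb else -math.inf, na + nb - 2, 0.0, True)
    if pooled:
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = math.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    else:
        se = math.sqrt(va / na + vb / nb)
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    t = (ma - mb) / se
    p = 2.0 * stats.t.sf(abs(t), df)
    return TTestResult(t, df, p)


@dataclass
class AnovaResult:
    """Effect table of a mixed-design ANOVA."""

    table: pd.DataFrame
    degenerate: bool = False

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]

    def p(self, name: str) -> float:
        return float(self.effect(name)["p"])


def _f_row(name, ss, df, ss_err, df_err):
    ms = ss / df if df > 0 else 0.0
    ms_err = ss_err / df_err if df_err > 0 else 0.0
    if ms_err == 0.0:
        f = 0.0
        p = 1.0
    else:
        f = ms / ms_err
        p = float(stats.f.sf(f, df, df_err))
    return {"effect": name, "SS": ss, "df": df, "MS": ms, "F": f, "p": p}


def _check_balance(df, subject, within, between_cols):
    levels = sorted(df[within].unique())
    bad = []
    for sid, sub in df.groupby(subject):
        if sorted(sub[within]) != levels:
            bad.append(sid)
    if bad:
        raise ValueError(
            f"unbalanced table: subjects missing within-levels: {bad}"
        )
    for col in between_cols:
        n_lab = df.groupby(subject)[col].nunique()
        off = list(n_lab[n_lab != 1].index)
        if off:
            raise ValueError(f"subjects with multiple {col} labels: {off}")


def mixed_anova(
    table: pd.DataFrame,
    dv: str,
    subject: str = "subject",
    between: str = "group",
    within: str = "block",
    second_between: str | None = None,
) -> AnovaResult:
    """Split-plot ANOVA: between-subject factor(s) × a repeated within factor.

    Between effects are tested against subjects-within-groups; the within
    factor and its interactions against the within × subjects residual.
    Requires a complete table (every subject at every within level); with
    two between factors, equal cell sizes.  An all-constant table reports
    zero SS / F with a warning flag rather than failing.
    """
    cols = [subject, between, within, dv] + (
        [second_between] if second_between else []
    )
    df = table[cols].dropna()
    if df[dv].isna().any() or not np.all(np.isfinite(df[dv])):
        raise ValueError("non-finite metric values")
    between_cols = [between] + ([second_between] if second_between else [])
    _check_balance(df, subject, within, between_cols)

    y = df[dv].to_numpy(dtype=float)
    grand = y.mean()
    ss_total = float(np.sum((y - grand) ** 2))
    B = df[within].nunique()
    subj_means = df.groupby(subject)[dv].mean()
    N = len(subj_means)
    ss_subjects = float(B * np.sum((subj_means - grand) ** 2))

    cell = df.groupby(between_cols)[dv]
    subj_groups = df.groupby(subject)[between_cols[0]].first()
    if second_between:
        counts = df.groupby(between_cols)[subject].nunique()
        if counts.nunique() != 1:
            raise ValueError("two between factors require equal cell sizes")
        if df.groupby(subject)[second_between].nunique().max() != 1:
            raise ValueError("second between factor varies within subject")
    else:
        gsizes = df.groupby(subject)[between].first().value_counts()
        if gsizes.min() < 2:
            raise ValueError("need >= 2 subjects per group")

    def ss_of(cols_):
        """Between-subject SS of the cell means over ``cols_`` (weighted)."""
        means = df.groupby(cols_)[dv].mean()
        n_subj = df.groupby(cols_)[subject].nunique()
        return float(B * np.sum(n_subj * (means - grand) ** 2))

    rows = []
    if second_between:
        ss_a = ss_of([between])
        ss_b = ss_of([second_between])
        ss_cells = ss_of(between_cols)
        ss_ab = ss_cells - ss_a - ss_b
        la = df[between].nunique()
        lb = df[second_between].nunique()
        ss_subj_err = ss_subjects - ss_cells
        df_subj_err = N - la * lb
        between_effects = [
            (between, ss_a, la - 1),
            (second_between, ss_b, lb - 1),
            (f"{between}*{second_between}", ss_ab, (la - 1) * (lb - 1)),
        ]
    else:
        ss_a = ss_of([between])
        la = df[between].nunique()
        ss_subj_err = ss_subjects - ss_a
        df_subj_err = N - la
        between_effects = [(between, ss_a, la - 1)]

    # within-subject part
    block_means = df.groupby(within)[dv].mean()
    ss_block = float(N * np.sum((block_means - grand) ** 2))
    within_effects = [(within, ss_block, B - 1)]

    def ss_inter(between_cols_):
        gb = df.groupby(between_cols_ + [within])[dv].mean()
        nsub = df.groupby(between_cols_)[subject].nunique()
        total = 0.0
        for key_b, nb in nsub.items():
            key_b = key_b if isinstance(key_b, tuple) else (key_b,)
            gmean = df.groupby(between_cols_)[dv].mean().loc[
                key_b if len(key_b) > 1 else key_b[0]
            ]
            for lvl in df[within].unique():
                cellm = gb.loc[key_b + (lvl,)]
                bm = block_means.loc[lvl]
                total += nb * (cellm - gmean - bm + grand) ** 2
        return float(total)

    if second_between:
        ss_wa = ss_inter([between])
        ss_wb = ss_inter([second_between])
        ss_wcells = ss_inter(between_cols)
        ss_wab = ss_wcells - ss_wa - ss_wb
        within_effects += [
            (f"{within}*{between}", ss_wa, (B - 1) * (la - 1)),
            (f"{within}*{second_between}", ss_wb, (B - 1) * (lb - 1)),
            (
                f"{within}*{between}*{second_between}",
                ss_wab,
                (B - 1) * (la - 1) * (lb - 1),
            ),
        ]
        ss_explained_w = ss_wcells + ss_block
        df_w_err = (N - la * lb) * (B - 1)
    else:
        ss_wa = ss_inter([between])
        within_effects += [(f"{within}*{between}", ss_wa, (B - 1) * (la - 1))]
        ss_explained_w = ss_wa + ss_block
        df_w_err = (N - la) * (B - 1)

    ss_within_total = ss_total - ss_subjects
    ss_w_err = max(ss_within_total - ss_explained_w, 0.0)

    degenerate = ss_total == 0.0
    if degenerate:
        warnings.warn("all values equal: every SS is 0, F reported as 0", stacklevel=2)

    for name, ss, dfe in between_effects:
        rows.append(_f_row(name, max(ss, 0.0), dfe, ss_subj_err, df_subj_err))
    rows.append(
        {
            "effect": "subjects(within groups)",
            "SS": ss_subj_err,
            "df": df_subj_err,
            "MS": ss_subj_err / df_subj_err if df_subj_err else 0.0,
            "F": np.nan,
            "p": np.nan,
        }
    )
    for name, ss, dfe in within_effects:
        rows.append(_f_row(name, max(ss, 0.0), dfe, ss_w_err, df_w_err))
    rows.append(
        {
            "effect": f"{within}*subjects(within groups)",
            "SS": ss_w_err,
            "df": df_w_err,
            "MS": ss_w_err / df_w_err if df_w_err else 0.0,
            "F": np.nan,
            "p": np.nan,
        }
    )
    return AnovaResult(pd.DataFrame(rows), degenerate)


def age_correlation(
    table: pd.DataFrame,
    metric: str,
    group: str = "group",
    age: str = "age",
    subject: str = "subject",
) -> pd.DataFrame:
    """Pearson correlation of a per-subject mean metric with age, per group.

    r is converted to t = r·sqrt((n−2)/(1−r²)) with a two-sided p.
    """
    rows = []
    per_subj = table.groupby([subject, group], observed=True).agg(
        value=(metric, "mean"), age=(age, "first")
    )
    for g, sub in per_subj.groupby(group, observed=True):
        x = sub["age"].to_numpy(dtype=float)
        v = sub["value"].to_numpy(dtype=float)
        if len(v) < 3:
            raise ValueError(f"group {g!r}: need >= 3 subjects")
        if np.std(v) == 0.0 or np.std(x) == 0.0:
            raise ValueError(f"group {g!r}: constant metric or age")
        r = float(np.corrcoef(x, v)[0, 1])
        n = len(v)
        if abs(r) >= 1.0:
            t, p = math.copysign(math.inf, r), 0.0
        else:
            t = r * math.sqrt((n - 2) / (1.0 - r * r))
            p = 2.0 * stats.t.sf(abs(t), n - 2)
        rows.append({"group": g, "n": n, "r": r, "t": t, "p": p})
    return pd.DataFrame(rows)


def pairwise_group_tests(
    table: pd.DataFrame,
    dv: str,
    group: str = "group",
    pooled: bool = True,
) -> pd.DataFrame:
    """All pairwise two-sample t tests between groups, Holm-adjusted.

    Provided as the post-hoc surface in place of stepwise range procedures
    that lack familywise error control guarantees.
    """
    groups = sorted(table[group].unique())
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            res = two_sample_t(
                table.loc[table[group] == a, dv],
                table.loc[table[group] == b, dv],
                pooled=pooled,
            )
            rows.append({"group_a": a, "group_b": b, "t": res.t, "df": res.df, "p": res.p})
    out = pd.DataFrame(rows)
    if len(out):
        order = np.argsort(out["p"].to_numpy())
        m = len(out)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * out["p"].iloc[idx])
            adj[idx] = min(running, 1.0)
        out["p_holm"] = adj
    return out
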