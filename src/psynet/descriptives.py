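"""Group-comparison descriptives: pooled t, Cohen's d, chi-square, Pearson r.

The t statistic is Student's pooled-variance t (df = n1 + n2 - 2), reported
as |t| with a two-sided p.  Chi-square is the Pearson statistic computed
from the expected-count formula, with Yates continuity correction applied
to 2x2 tables by default (the convention that reproduces the study's
printed gender statistic).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError


def pooled_t(m1, sd1, n1, m2, sd2, n2) -> tuple[float, int]:
    """|t| and df of the pooled-variance two-sample t-test from summaries."""
    if n1 < 2 or n2 < 2:
        raise ParameterError("both groups need n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ParameterError("standard deviations must be non-negative")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    if sp2 == 0:
        if m1 == m2:
            raise ParameterError("undefined statistic: zero variance, equal means")
        return math.inf, df
    t = abs(m1 - m2) / math.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    return t, df


def cohen_d(m1, sd1, n1, m2, sd2, n2) -> float:
    """|m1 - m2| / pooled SD."""
    df = n1 + n2 - 2
    sp = math.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df)
    if sp == 0:
        if m1 == m2:
            return 0.0
        raise ParameterError("undefined effect size: zero pooled SD")
    return abs(m1 - m2) / sp


def chi_square(table, continuity: bool | None = None) -> tuple[float, int]:
    """Pearson chi-square from the expected-count formula.

    ``continuity=None`` applies Yates' correction iff the table is 2x2.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ParameterError("need at least a 2x2 table")
    if (obs < 0).any():
        raise ParameterError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if (rows == 0).any() or (cols == 0).any():
        raise ParameterError("degenerate table: a zero marginal")
    expected = np.outer(rows, cols) / total
    if continuity is None:
        continuity = obs.shape == (2, 2)
    diff = np.abs(obs - expected)
    if continuity and obs.shape == (2, 2):
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return chi2, df


def t_p_value(t: float, df: int) -> float:
    return float(2.0 * stats.t.sf(abs(t), df))


def chi2_p_value(chi2: float, df: int) -> float:
    return float(stats.chi2.sf(chi2, df))


@dataclass
class CorrelationTable:
    """Pairwise Pearson correlations with two-sided p-values."""

    r: pd.DataFrame
    p: pd.DataFrame


def correlation_table(frame: pd.DataFrame, variables=None) -> CorrelationTable:
    """Pearson correlation matrix over the given columns.

    Raises on constant columns (the correlation is undefined there).
    """
    cols = list(variables) if variables is not None else list(frame.columns)
    data = frame[cols].apply(pd.to_numeric, errors="coerce").dropna()
    if len(data) < 3:
        raise ParameterError("need at least 3 complete rows")
    for c in cols:
        if data[c].nunique() < 2:
            raise ParameterError(f"undefined correlation: column {c!r} is constant")
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    for a in range(k):
        for b in range(a + 1, k):
            res = stats.pearsonr(data[cols[a]], data[cols[b]])
            r[a, b] = r[b, a] = res.statistic
            p[a, b] = p[b, a] = res.pvalue
    return CorrelationTable(
        pd.DataFrame(r, index=cols, columns=cols),
        pd.DataFrame(p, index=cols, columns=cols),
    )


def group_comparison_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Demographics-style comparison of depressed vs control groups.

    Continuous variables get mean/SD per group with pooled t and d;
    categorical variables (gender, education) get counts/percentages with
    chi-square.  Expects the columns produced by ``scales.score_sample``.
    """
    dep = scored[scored["group"] == "depressed"]
    ctl = scored[scored["group"] == "control"]
    rows = []

    def cont_row(name, col):
        m1, s1, n1 = dep[col].mean(), dep[col].std(ddof=1), len(dep)
        m2, s2, n2 = ctl[col].mean(), ctl[col].std(ddof=1), len(ctl)
        t, df = pooled_t(m1, s1, n1, m2, s2, n2)
        rows.append({
            "variable": name, "dep_mean": m1, "dep_sd": s1,
            "ctl_mean": m2, "ctl_sd": s2, "statistic": t, "df": df,
            "p": t_p_value(t, df), "cohen_d": cohen_d(m1, s1, n1, m2, s2, n2),
            "test": "t",
        })

    def cat_row(name, col):
        levels = sorted(scored[col].dropna().unique())
        counts = np.array([
            [int((dep[col] == lv).sum()) for lv in levels],
            [int((ctl[col] == lv).sum()) for lv in levels],
        ])
        chi2, df = chi_square(counts)
        rows.append({
            "variable": name, "dep_counts": counts[0].tolist(),
            "ctl_counts": counts[1].tolist(), "levels": list(levels),
            "statistic": chi2, "df": df, "p": chi2_p_value(chi2, df),
            "test": "chi2",
        })

    if "age" in scored:
        cont_row("age", "age")
    if "gender" in scored:
        cat_row("gender", "gender")
    if "education" in scored:
        cat_row("education", "education")
    cont_row("depressive symptoms (PHQ-9)", "phq9_total")
    cont_row("self-efficacy (GSES)", "gses_total")
    return pd.DataFrame(rows)
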