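"""Descriptive group comparisons from raw data or printed summaries.

Cohort demographics tables usually print only group means, standard
deviations and counts.  These helpers recompute the standard tests
(one-way ANOVA, pooled two-sample t, Pearson chi-square) directly from
those moments, so a published table row can be checked without the raw
data.  The pooled-variance t is used because its degrees of freedom
(n_a + n_b - 2) are what such tables report.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .errors import ValidationError


@dataclass(frozen=True)
class GroupSummary:
    """Printed per-group moments: n, mean, sd."""

    label: str
    n: int
    mean: float
    sd: float

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValidationError("group size must be at least 2")
        if self.sd < 0:
            raise ValidationError("sd must be nonnegative")

    @classmethod
    def from_values(cls, label: str, values) -> "GroupSummary":
        v = np.asarray(values, dtype=float)
        return cls(label=label, n=len(v), mean=float(v.mean()),
                   sd=float(v.std(ddof=1)))


@dataclass
class AnovaResult:
    f: float
    df_between: int
    df_within: int
    p: float


@dataclass
class TTestResult:
    t: float
    df: int
    p: float


@dataclass
class ChiSquareResult:
    chi2: float
    df: int
    p: float


def anova_from_summary(groups: Sequence[GroupSummary]) -> AnovaResult:
    """One-way ANOVA F from per-group (n, mean, sd).

    F = [sum n_g (m_g - grand_mean)^2 / (G-1)] /
        [sum (n_g - 1) s_g^2 / sum (n_g - 1)].
    """
    if len(groups) < 2:
        raise ValidationError("ANOVA needs at least two groups")
    n = np.array([g.n for g in groups], dtype=float)
    m = np.array([g.mean for g in groups])
    s = np.array([g.sd for g in groups])
    grand = float((n * m).sum() / n.sum())
    df_between = len(groups) - 1
    df_within = int(n.sum()) - len(groups)
    ms_between = float((n * (m - grand) ** 2).sum()) / df_between
    ms_within = float(((n - 1) * s**2).sum()) / df_within
    if ms_within == 0:
        raise ValidationError("zero pooled variance")
    f = ms_between / ms_within
    return AnovaResult(f=f, df_between=df_between, df_within=df_within,
                       p=float(stats.f.sf(f, df_between, df_within)))


def t_from_summary(a: GroupSummary, b: GroupSummary) -> TTestResult:
    """Pooled-variance two-sample t from printed moments; df = n_a + n_b - 2."""
    df = a.n + b.n - 2
    pooled_var = ((a.n - 1) * a.sd**2 + (b.n - 1) * b.sd**2) / df
    if pooled_var == 0:
        raise ValidationError("zero pooled variance")
    se = np.sqrt(pooled_var * (1 / a.n + 1 / b.n))
    t = (a.mean - b.mean) / se
    return TTestResult(t=float(t), df=df,
                       p=float(2 * stats.t.sf(abs(t), df)))


def chi_square(counts) -> ChiSquareResult:
    """Pearson chi-square of independence on a groups x categories table.

    No continuity correction (matching the convention of demographic
    tables); df = (rows - 1)(cols - 1).  Zero marginals are rejected.
    """
    table = np.asarray(counts, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValidationError("counts must be a 2-D table with >= 2 rows/cols")
    if np.any(table < 0):
        raise ValidationError("counts must be nonnegative")
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValidationError("zero row or column marginal")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return ChiSquareResult(chi2=float(chi2), df=int(df), p=float(p))


def summary_table(rows: dict[str, Sequence[GroupSummary]], path=None):
    """Demographics-table TSV: one row per variable, 'mean (sd)' per group,
    plus the recomputed ANOVA F (3+ groups) or pooled t (2 groups).

    ``rows`` maps a variable name to its per-group summaries.  Returns the
    DataFrame; writes it to ``path`` when given.
    """
    import pandas as pd

    out = []
    for name, groups in rows.items():
        record = {"variable": name}
        for g in groups:
            record[g.label] = f"{g.mean:g} ({g.sd:g})"
        if len(groups) == 2:
            res = t_from_summary(*groups)
            record.update(statistic=round(res.t, 3), df=str(res.df),
                          p=round(res.p, 4))
        else:
            res = anova_from_summary(list(groups))
            record.update(statistic=round(res.f, 3),
                          df=f"({res.df_between};{res.df_within})",
                          p=round(res.p, 4))
        out.append(record)
    frame = pd.DataFrame(out)
    if path is not None:
        frame.to_csv(path, sep="\t", index=False)
    return frame
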