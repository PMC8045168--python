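"""Group summaries and two-sample t tests for the sex comparison tables.

The reporting layer mirrors the study design: per-variable Male / Female /
All rows as mean +/- SD, with a two-sample t test between sexes. The default
t method is the pooled (Student) test with df = n1 + n2 - 2, which is what
the published screw-length/diameter t values reproduce; Welch is available
as an alternative. Combined "All" rows are computed exactly from the group
summaries via the total sum-of-squares decomposition, not by re-averaging
raw data, so they can also be produced from printed summary tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import AcroplanError, DegenerateInputError

__all__ = [
    "GroupSummary",
    "TTestResult",
    "summarize_group",
    "pooled_mean_sd",
    "t_from_summary",
    "t_from_data",
    "build_tables",
    "format_table",
    "TABLE_VARIABLES",
]


@dataclass(frozen=True)
class GroupSummary:
    variable: str
    n: int
    mean: float
    sd: float

    def __post_init__(self):
        if self.n < 2:
            raise DegenerateInputError("a group summary needs n >= 2")
        if self.sd < 0 or not np.isfinite(self.mean) or not np.isfinite(self.sd):
            raise AcroplanError("invalid group summary")


@dataclass(frozen=True)
class TTestResult:
    variable: str
    t: float
    df: float
    p: float
    method: str  # 'pooled' | 'welch'


def summarize_group(values, variable: str = "") -> GroupSummary:
    """Mean and SD (n-1 denominator) of one group."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise DegenerateInputError("need at least 2 values to summarize")
    if not np.isfinite(x).all():
        raise AcroplanError("non-finite values in group")
    return GroupSummary(variable=variable, n=int(x.size),
                        mean=float(x.mean()), sd=float(x.std(ddof=1)))


def pooled_mean_sd(g1: GroupSummary, g2: GroupSummary) -> GroupSummary:
    """Exact combined mean/SD of two groups from their summaries.

    SS_total = (n1-1) s1^2 + (n2-1) s2^2 + n1 (m1-m)^2 + n2 (m2-m)^2 with
    m the weighted mean; SD = sqrt(SS_total / (n1+n2-1)). For any raw sample
    split in two this reproduces the full-sample mean/SD exactly.
    """
    n1, n2 = g1.n, g2.n
    n = n1 + n2
    m = (n1 * g1.mean + n2 * g2.mean) / n
    ss = ((n1 - 1) * g1.sd**2 + (n2 - 1) * g2.sd**2
          + n1 * (g1.mean - m) ** 2 + n2 * (g2.mean - m) ** 2)
    return GroupSummary(variable=g1.variable or g2.variable, n=n,
                        mean=float(m), sd=float(np.sqrt(ss / (n - 1))))


def t_from_summary(g1: GroupSummary, g2: GroupSummary, method: str = "pooled") -> TTestResult:
    """Two-sample t test from group summaries (two-sided p).

    Pooled: t = (m1 - m2) / sqrt(sp^2 (1/n1 + 1/n2)), sp^2 the pooled
    variance, df = n1 + n2 - 2. Welch uses the Welch-Satterthwaite df.
    Zero pooled variance: t = 0 when the means agree, +/-inf otherwise.
    """
    name = g1.variable or g2.variable
    diff = g1.mean - g2.mean
    if method == "pooled":
        df = g1.n + g2.n - 2
        sp2 = ((g1.n - 1) * g1.sd**2 + (g2.n - 1) * g2.sd**2) / df
        if sp2 <= 0:
            t = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / np.sqrt(sp2 * (1.0 / g1.n + 1.0 / g2.n))
            p = 2.0 * float(_sps.t.sf(abs(t), df))
        return TTestResult(variable=name, t=float(t), df=float(df), p=p, method="pooled")
    if method == "welch":
        if g1.sd == 0 and g2.sd == 0:
            t = 0.0 if diff == 0 else float(np.sign(diff)) * float("inf")
            return TTestResult(variable=name, t=t, df=float(g1.n + g2.n - 2),
                               p=1.0 if diff == 0 else 0.0, method="welch")
        t, p = _sps.ttest_ind_from_stats(g1.mean, g1.sd, g1.n, g2.mean, g2.sd, g2.n,
                                         equal_var=False)
        v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
        return TTestResult(variable=name, t=float(t), df=float(df), p=float(p), method="welch")
    raise AcroplanError(f"unknown t method {method!r}")


def t_from_data(x1, x2, method: str = "pooled", variable: str = "") -> TTestResult:
    """Two-sample t test from raw data; equals the summary route exactly."""
    return t_from_summary(summarize_group(x1, variable), summarize_group(x2, variable),
                          method=method)


# variable -> column label, grouped per table as in the study layout
TABLE_VARIABLES = {
    "medial_screw": [("ms_length", "Length (mm)"), ("ms_diameter", "Diameter (mm)"),
                     ("L1", "L1 (mm)"), ("L2", "L2 (mm)")],
    "lateral_screw": [("ls_length", "Length (mm)"), ("ls_diameter", "Diameter (mm)"),
                      ("L3", "L3 (mm)"), ("L4", "L4 (mm)")],
    "angles": [("alpha", "alpha (deg)"), ("beta", "beta (deg)")],
}


def build_tables(cohort: pd.DataFrame, method: str = "pooled") -> dict:
    """Three comparison tables (medial screw, lateral screw, angles).

    ``cohort`` must have a ``sex`` column with both 'M' and 'F' plus the
    measurement columns. Returns, per table, a dict mapping each variable to
    its Male/Female/All :class:`GroupSummary` and :class:`TTestResult`.
    """
    cohort = pd.DataFrame(cohort)
    sexes = set(cohort.get("sex", pd.Series(dtype=str)))
    if not {"M", "F"} <= sexes:
        raise AcroplanError("cohort must contain both male and female subjects")
    males = cohort[cohort["sex"] == "M"]
    females = cohort[cohort["sex"] == "F"]
    out: dict = {}
    for table, cols in TABLE_VARIABLES.items():
        rows = {}
        for col, label in cols:
            if col not in cohort.columns:
                continue
            gm = summarize_group(males[col], label)
            gf = summarize_group(females[col], label)
            rows[col] = {
                "label": label,
                "male": gm,
                "female": gf,
                "all": pooled_mean_sd(gm, gf),
                "ttest": t_from_summary(gm, gf, method=method),
            }
        out[table] = rows
    return out


def _fmt_p(p: float) -> str:
    # study-style: 3 decimals, values < 0.0005 printed as 0.000
    return f"{p:.3f}"


def format_table(rows: dict) -> pd.DataFrame:
    """One table as a DataFrame with All/Male/Female/t/P rows, 'mean +/- SD' cells."""
    cols = [r["label"] for r in rows.values()]
    data = {"Group": ["All", "Male", "Female", "t", "P"]}
    for col, r in rows.items():
        cells = [f"{r[k].mean:.2f} ± {r[k].sd:.2f}" for k in ("all", "male", "female")]
        cells += [f"{r['ttest'].t:.3f}", _fmt_p(r["ttest"].p)]
        data[r["label"]] = cells
    df = pd.DataFrame(data)
    df.columns = ["Group"] + cols
    return df
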