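"""Cohort-level statistics.

Mean +/- SD summaries per metric and exercise phase, skewness/kurtosis
normality screening, Welch's unpaired t-test (Control vs Rest contrast) and
ordinary least-squares regression between continuous variables. Two-sided
significance at 0.05; no multiple-testing correction (one planned contrast
per metric).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_cohort import PhaseLabel

__all__ = [
    "TestResult",
    "normality_screen",
    "unpaired_ttest",
    "linear_fit",
    "summary_table",
    "METRIC_ORDER",
]

# row order of the published-style report
METRIC_ORDER = [
    "HR", "EDV", "ESV", "SV", "EF", "GPS", "GSS", "GLS", "GCS",
    "LVLF", "LVsysLF", "LVsysIm", "LVs", "LVdiaLF", "LVdiaIm",
    "omega_bar_peak", "VFT", "E/A",
]

PHASE_ORDER = [p.value for p in (
    PhaseLabel.CONTROL, PhaseLabel.REST, PhaseLabel.MID, PhaseLabel.PEAK,
    PhaseLabel.RECOVERY5, PhaseLabel.RECOVERY10,
)]

SKEW_LIMIT = 2.0  # |sample skewness| flagged non-normal beyond this
KURT_LIMIT = 4.0  # |excess kurtosis| flagged non-normal beyond this


@dataclass
class TestResult:
    statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def normality_screen(sample, *, skew_limit: float = SKEW_LIMIT,
                     kurt_limit: float = KURT_LIMIT):
    """Sample skewness and excess kurtosis with a pass/fail normality flag."""
    x = np.asarray(sample, float)
    if len(x) < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0:
        raise ValueError("zero-variance sample")
    skew = float(stats.skew(x))
    kurt = float(stats.kurtosis(x))  # excess (Fisher)
    return skew, kurt, bool(abs(skew) <= skew_limit and abs(kurt) <= kurt_limit)


def unpaired_ttest(a, b) -> TestResult:
    """Welch's two-sided unequal-variance t-test."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a) == 0 and np.var(b) == 0:
        raise ValueError("both groups have zero variance")
    res = stats.ttest_ind(a, b, equal_var=False)
    return TestResult(float(res.statistic), float(res.pvalue), len(a), len(b),
                      "welch-t two-sided")


def linear_fit(x, y):
    """Ordinary least squares y = slope*x + intercept.

    Returns (slope, intercept, r_squared, p_value); a constant y gives
    R^2 = 0 (no variance explained) with slope 0.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("constant predictor")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return (float(res.slope), float(res.intercept),
            float(res.rvalue**2), float(res.pvalue))


def summary_table(table: pd.DataFrame, *, derive_sv: bool = True) -> pd.DataFrame:
    """Published-style report: mean +/- SD per metric per phase, with a Welch
    p column comparing Control vs Rest where both groups are present.

    ``table`` holds long-format records with columns
    (subject, phase, metric, value); one value per (subject, phase, metric).
    SV is derived per subject as EDV - ESV before summarizing. Phases with no
    data appear as NaN columns (flagged in ``attrs['missing_phases']``).
    """
    required = {"subject", "phase", "metric", "value"}
    if not required.issubset(table.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    if table.empty:
        raise ValueError("empty cohort table")
    df = table.copy()
    df["phase"] = df["phase"].map(lambda p: p.value if isinstance(p, PhaseLabel) else str(p))
    if df.duplicated(["subject", "phase", "metric"]).any():
        dup = df[df.duplicated(["subject", "phase", "metric"], keep=False)]
        raise ValueError(f"duplicate records:\n{dup.head()}")

    if derive_sv and "SV" not in set(df["metric"]):
        wide = df[df["metric"].isin(["EDV", "ESV"])].pivot_table(
            index=["subject", "phase"], columns="metric", values="value"
        )
        if {"EDV", "ESV"}.issubset(wide.columns):
            sv = (wide["EDV"] - wide["ESV"]).dropna().reset_index()
            sv["metric"] = "SV"
            sv = sv.rename(columns={0: "value"})
            df = pd.concat([df, sv], ignore_index=True)

    phases = [p for p in PHASE_ORDER if p in set(df["phase"])]
    missing = [p for p in PHASE_ORDER if p not in phases]
    metrics = [m for m in METRIC_ORDER if m in set(df["metric"])]
    metrics += [m for m in sorted(set(df["metric"])) if m not in metrics]

    rows = {}
    pvals = {}
    for m in metrics:
        sub = df[df["metric"] == m]
        row = {}
        for ph in phases:
            vals = sub.loc[sub["phase"] == ph, "value"].to_numpy(float)
            vals = vals[np.isfinite(vals)]
            if len(vals) < 2:
                row[(ph, "mean")] = vals[0] if len(vals) else np.nan
                row[(ph, "sd")] = np.nan
            else:
                row[(ph, "mean")] = float(np.mean(vals))
                row[(ph, "sd")] = float(np.std(vals, ddof=1))
        rows[m] = row
        a = sub.loc[sub["phase"] == PhaseLabel.CONTROL.value, "value"].to_numpy(float)
        b = sub.loc[sub["phase"] == PhaseLabel.REST.value, "value"].to_numpy(float)
        a, b = a[np.isfinite(a)], b[np.isfinite(b)]
        if len(a) >= 2 and len(b) >= 2 and (np.var(a) > 0 or np.var(b) > 0):
            pvals[m] = unpaired_ttest(a, b).p_value
        else:
            pvals[m] = np.nan

    out = pd.DataFrame.from_dict(rows, orient="index")
    out.columns = pd.MultiIndex.from_tuples(out.columns)
    out[("Control_vs_Rest", "p")] = pd.Series(pvals)
    out.index.name = "metric"
    out.attrs["missing_phases"] = missing
    return out


def format_summary_markdown(summary: pd.DataFrame) -> str:
    """Render a summary table as a mean +/- SD Markdown table."""
    phases = sorted({c[0] for c in summary.columns if c[0] != "Control_vs_Rest"},
                    key=lambda p: PHASE_ORDER.index(p) if p in PHASE_ORDER else 99)
    lines = ["| Metric | " + " | ".join(phases) + " | p (Control vs Rest) |",
             "|" + "---|" * (len(phases) + 2)]
    for m, row in summary.iterrows():
        cells = []
        for ph in phases:
            mean, sd = row.get((ph, "mean"), np.nan), row.get((ph, "sd"), np.nan)
            cells.append("-" if not np.isfinite(mean) else f"{mean:.1f}±{sd:.1f}")
        p = row.get(("Control_vs_Rest", "p"), np.nan)
        ptxt = "-" if not np.isfinite(p) else f"{p:.3f}"
        lines.append(f"| {m} | " + " | ".join(cells) + f" | {ptxt} |")
    return "\n".join(lines)
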