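"""Cohort-level statistics: per-structure summaries, metric correlations,
and the two-sample Kolmogorov-Smirnov comparison between structures whose
DVHs pass and fail the flagging rule.

The cohort table has one row per (patient, structure) with the contour
metrics (Dice, HD95, Eff) and the DVH pass/fail outcome.  The KS statistic
sup_t |F_pass(t) - F_fail(t)| measures how well each contour metric
separates the two outcome groups; the metric with the largest statistic is
the most predictive of DVH disagreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ArgumentError,
    DegenerateSampleError,
    GroupingError,
    SampleSizeError,
)
from .names import base_name, is_ptv

__all__ = [
    "GroupComparison",
    "ks_two_sample",
    "pearson_r",
    "summarize_cohort",
    "compare_pass_fail",
    "most_predictive",
    "format_percent_summary",
]

#: Column schema of a cohort table.
COHORT_COLUMNS = [
    "patient",
    "structure",
    "dice",
    "hd95",
    "eff",
    "dvh_pass",
    "zero_dose",
]


@dataclass
class GroupComparison:
    """Two-sample KS comparison of one metric between pass and fail groups."""

    metric: str
    statistic: float  # in [0, 1]
    p_value: float
    pass_mean: float
    pass_sd: float
    fail_mean: float
    fail_sd: float
    n_pass: int
    n_fail: int

    def as_dict(self) -> dict:
        return {
            "metric": self.metric,
            "ks_statistic": self.statistic,
            "p_value": self.p_value,
            "pass_mean": self.pass_mean,
            "pass_sd": self.pass_sd,
            "fail_mean": self.fail_mean,
            "fail_sd": self.fail_sd,
            "n_pass": self.n_pass,
            "n_fail": self.n_fail,
        }


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample KS statistic and asymptotic p-value.

    The statistic is the supremum over t of the gap between the two
    empirical CDFs; the p-value uses the asymptotic two-sample KS
    distribution (appropriate for cohort-sized groups).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size < 2 or y.size < 2:
        raise SampleSizeError(
            f"KS test requires >= 2 values per sample, got {x.size} and {y.size}"
        )
    res = sps.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> float:
    """Sample Pearson product-moment correlation of two paired samples."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size != y.size:
        raise ArgumentError("paired samples must have equal length")
    if x.size < 3:
        raise SampleSizeError(f"correlation requires >= 3 pairs, got {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise DegenerateSampleError("zero-variance sample in correlation")
    return float(sps.pearsonr(x, y).statistic)


def _summary_rows(df: pd.DataFrame, label: str, metrics) -> dict:
    row = {"group": label, "n": len(df)}
    for m in metrics:
        vals = df[m].dropna().to_numpy(dtype=float)
        row[f"{m}_mean"] = float(vals.mean()) if vals.size else float("nan")
        # sample SD (n-1); reported as 0 for singletons, flagged via n
        row[f"{m}_sd"] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return row


def summarize_cohort(
    table: pd.DataFrame,
    metrics=("dice", "hd95", "eff"),
    group_lateral_pairs: bool = True,
) -> pd.DataFrame:
    """Mean +/- sample SD of each metric per structure and per class.

    Groups rows by structure name (left/right pairs merged by default via
    laterality-stripped keys) and appends ``OAR``, ``PTV`` and ``ALL``
    aggregate rows.  SD uses the n-1 denominator; single-row groups report
    SD 0 and are identifiable by ``n == 1``.
    """
    if table.empty:
        raise ArgumentError("cohort table is empty")
    df = table.copy()
    keyfn = base_name if group_lateral_pairs else lambda s: s
    df["_group"] = [keyfn(s) for s in df["structure"]]
    rows = [
        _summary_rows(g, name, metrics)
        for name, g in df.groupby("_group", sort=True)
    ]
    oar = df[[not is_ptv(s) for s in df["structure"]]]
    ptv = df[[is_ptv(s) for s in df["structure"]]]
    if len(oar):
        rows.append(_summary_rows(oar, "OAR", metrics))
    if len(ptv):
        rows.append(_summary_rows(ptv, "PTV", metrics))
    rows.append(_summary_rows(df, "ALL", metrics))
    return pd.DataFrame(rows)


def format_percent_summary(mean: float, sd: float) -> str:
    """Render a fractional mean +/- SD as the conventional percent string,
    e.g. (0.244, 0.271) -> ``"24.4% ± 27.1%"``."""
    return f"{100 * mean:.1f}% ± {100 * sd:.1f}%"


def compare_pass_fail(
    table: pd.DataFrame,
    metrics=("dice", "hd95", "eff"),
    exclude_zero_dose: bool = True,
) -> list[GroupComparison]:
    """KS-compare each contour metric between DVH-pass and DVH-fail rows.

    Structures receiving no dose pass the DVH rule vacuously (any two
    contours agree under zero dose) and are excluded by default so they do
    not dilute the contrast.  Raises :class:`GroupingError` when either
    group is empty.
    """
    df = table
    if exclude_zero_dose and "zero_dose" in df.columns:
        df = df[~df["zero_dose"].astype(bool)]
    passing = df[df["dvh_pass"].astype(bool)]
    failing = df[~df["dvh_pass"].astype(bool)]
    for name, group in (("pass", passing), ("fail", failing)):
        if len(group) == 0:
            raise GroupingError(f"the '{name}' group is empty")
    out = []
    for m in metrics:
        p = passing[m].dropna().to_numpy(dtype=float)
        f = failing[m].dropna().to_numpy(dtype=float)
        stat, pval = ks_two_sample(p, f)
        out.append(
            GroupComparison(
                metric=m,
                statistic=stat,
                p_value=pval,
                pass_mean=float(p.mean()),
                pass_sd=float(p.std(ddof=1)) if p.size > 1 else 0.0,
                fail_mean=float(f.mean()),
                fail_sd=float(f.std(ddof=1)) if f.size > 1 else 0.0,
                n_pass=p.size,
                n_fail=f.size,
            )
        )
    return out


def most_predictive(comparisons: list[GroupComparison]) -> GroupComparison:
    """The comparison with the largest KS statistic (ties: first listed)."""
    if not comparisons:
        raise ArgumentError("no comparisons given")
    return max(comparisons, key=lambda c: c.statistic)
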