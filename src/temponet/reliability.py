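"""Test-retest reliability via ICC(3,1).

ICC(3,1) is the single-measure intraclass correlation from a two-way mixed
model with subjects random and scan session fixed:

    ICC(3,1) = (BMS - EMS) / (BMS + (k - 1) * EMS)

where BMS is the between-subjects mean square, EMS the residual
(subject x scan interaction) mean square after removing the scan main
effect, and k the number of repeated scans. Removing the scan main effect
makes the estimate invariant to a pure session shift, the property that
distinguishes ICC(3,1) from ICC(1,1).

Per metric and scope, ICC is computed at every density; the "overall ICC"
is the plain mean across densities (with its SD), classified as
poor (< 0.4), moderate (0.4-0.6), good (0.6-0.75) or excellent (> 0.75).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import Cohort, ValidationError


@dataclass(frozen=True)
class IccResult:
    scope: str
    metric_name: str
    per_density: Mapping[float, float]
    overall_icc: float
    overall_sd: float
    reliability_class: str


def icc_3_1(panel: np.ndarray) -> float:
    """ICC(3,1) of an n-subjects x k-scans panel.

    Returns NaN (with a warning) when all cells are identical, where the
    ratio is undefined.
    """
    panel = np.asarray(panel, dtype=float)
    if panel.ndim != 2:
        raise ValidationError("panel must be 2-D (subjects x scans)")
    n, k = panel.shape
    if n < 2 or k < 2:
        raise ValidationError("need at least 2 subjects and 2 scans")
    if np.isnan(panel).any():
        raise ValidationError("panel has missing cells; no imputation is done")
    grand = panel.mean()
    ss_subj = k * ((panel.mean(axis=1) - grand) ** 2).sum()
    ss_scan = n * ((panel.mean(axis=0) - grand) ** 2).sum()
    ss_total = ((panel - grand) ** 2).sum()
    ss_err = ss_total - ss_subj - ss_scan
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    denom = bms + (k - 1) * ems
    if denom == 0:
        warnings.warn("all panel values identical; ICC undefined", stacklevel=2)
        return float("nan")
    return float((bms - ems) / denom)


def icc_confidence_interval(
    panel: np.ndarray, alpha: float = 0.05
) -> tuple[float, float]:
    """F-distribution 95% CI for ICC(3,1) (optional extension).

    Uses the standard interval based on F = BMS/EMS with (n-1) and
    (n-1)(k-1) degrees of freedom.
    """
    panel = np.asarray(panel, dtype=float)
    n, k = panel.shape
    grand = panel.mean()
    ss_subj = k * ((panel.mean(axis=1) - grand) ** 2).sum()
    ss_scan = n * ((panel.mean(axis=0) - grand) ** 2).sum()
    ss_err = ((panel - grand) ** 2).sum() - ss_subj - ss_scan
    bms = ss_subj / (n - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    if ems == 0:
        return (1.0, 1.0)
    fobs = bms / ems
    df1, df2 = n - 1, (n - 1) * (k - 1)
    fl = fobs / stats.f.ppf(1 - alpha / 2, df1, df2)
    fu = fobs * stats.f.ppf(1 - alpha / 2, df2, df1)
    return (
        float((fl - 1) / (fl + k - 1)),
        float((fu - 1) / (fu + k - 1)),
    )


def classify_icc(value: float) -> str:
    """Four-level qualitative bin of an overall ICC.

    The printed criterion leaves exactly 0.75 unassigned (good is
    [0.6, 0.75), excellent is > 0.75); 0.75 maps to good.
    """
    if np.isnan(value):
        return "undefined"
    if value < 0.4:
        return "poor"
    if value < 0.6:
        return "moderate"
    if value <= 0.75:
        return "good"
    return "excellent"


def _pivot_panel(
    group: pd.DataFrame, subjects: list[str], runs: list[str]
) -> np.ndarray:
    panel = group.pivot(index="subject", columns="run", values="value")
    missing = [
        (s, r)
        for s in subjects
        for r in runs
        if s not in panel.index or r not in panel.columns or pd.isna(panel.loc[s, r])
    ]
    if missing:
        raise ValidationError(f"unbalanced panel; missing cells: {missing[:10]}")
    return panel.loc[subjects, runs].to_numpy()


def icc_table(metrics: pd.DataFrame, cohort: Cohort) -> list[IccResult]:
    """Per-density ICC(3,1) plus density-averaged overall ICC per scope/metric.

    ``metrics`` is a long-form table of per-run values; every subject must
    have a value for each of the cohort's k >= 2 runs at every
    (scope, metric, density) cell.
    """
    if cohort.n_runs < 2:
        raise ValidationError("reliability needs at least 2 runs per subject")
    subjects = [s.subject_id for s in cohort.subjects]
    runs = sorted(metrics["run"].unique())
    results = []
    for (metric, scope), group in metrics.groupby(["metric", "scope"], sort=False):
        per_density: dict[float, float] = {}
        for density, cell in group.groupby("density", sort=True):
            per_density[float(density)] = icc_3_1(_pivot_panel(cell, subjects, runs))
        values = np.array(list(per_density.values()))
        overall = float(values.mean())
        sd = float(values.std(ddof=0)) if len(values) > 1 else 0.0
        results.append(
            IccResult(
                scope=scope,
                metric_name=metric,
                per_density=per_density,
                overall_icc=overall,
                overall_sd=sd,
                reliability_class=classify_icc(overall),
            )
        )
    return results


def icc_results_frame(results: list[IccResult]) -> pd.DataFrame:
    """Flatten IccResults to a TSV-ready frame (one row per scope/metric)."""
    rows = []
    for res in results:
        row = {
            "metric": res.metric_name,
            "scope": res.scope,
            "overall_icc": res.overall_icc,
            "overall_sd": res.overall_sd,
            "class": res.reliability_class,
        }
        row.update({f"d={d:g}": v for d, v in res.per_density.items()})
        rows.append(row)
    return pd.DataFrame(rows)
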