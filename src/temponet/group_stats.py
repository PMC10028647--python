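"""Sex and age effects on run-averaged network metrics.

Sex contrast: metrics are first averaged over runs, then over the density
grid per subject (the between-subjects stratum of a balanced split-plot
design, where density is the within-subject factor, is exactly the
analysis of the subject means). The sex main effect F is taken from an
OLS ANCOVA of the subject means on sex plus the covariates age, education
and mean framewise displacement.

Age association: partial Spearman correlation of the density-averaged
metric with age, adjusting for sex, education and motion — all variables
are mid-rank transformed, metric and age ranks are residualized on the
covariate ranks, and the Pearson correlation of the residuals is tested
with n - 2 - (#covariates) degrees of freedom.

Sex and age are tested in separate models; p-values are Bonferroni
corrected within families (2 tests at the global level, 2 x 9 = 18 at the
subnetwork level by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import Cohort, ValidationError


@dataclass(frozen=True)
class SexContrastResult:
    scope: str
    metric_name: str
    F: float
    p_uncorrected: float
    p_corrected: float
    direction: int  # sign of (female - male) adjusted difference
    n_tests: int


@dataclass(frozen=True)
class AgeCorrelationResult:
    scope: str
    metric_name: str
    rho: float
    p_uncorrected: float
    p_corrected: float
    n_tests: int


def average_runs(metrics: pd.DataFrame) -> pd.DataFrame:
    """Mean over runs, one record per (subject, density, scope, metric)."""
    counts = metrics.groupby("subject")["run"].nunique()
    if counts.nunique() > 1:
        raise ValidationError("unbalanced runs across subjects")
    averaged = (
        metrics.groupby(["subject", "density", "scope", "metric"], sort=False)[
            "value"
        ]
        .mean()
        .reset_index()
    )
    averaged.insert(1, "run", "mean-of-runs")
    return averaged


def _subject_density_means(
    metrics: pd.DataFrame, cohort: Cohort, scope: str, metric: str
) -> pd.DataFrame:
    """Per-subject mean over the density grid, joined with covariates."""
    sel = metrics[(metrics["scope"] == scope) & (metrics["metric"] == metric)]
    if sel.empty:
        raise ValidationError(f"no records for scope={scope!r}, metric={metric!r}")
    means = sel.groupby("subject")["value"].mean().rename("y")
    frame = cohort.to_frame().set_index("subject").join(means, how="inner")
    if frame["y"].isna().any() or len(frame) < len(cohort.subjects):
        raise ValidationError("metric table missing subjects present in cohort")
    return frame.reset_index()


def _design(frame: pd.DataFrame, with_interaction: bool = False) -> np.ndarray:
    female = (frame["sex"] == "female").to_numpy(dtype=float)
    cols = [np.ones(len(frame)), female]
    names = ["intercept", "female"]
    for cov in ("age", "education", "mean_fd"):
        x = frame[cov].to_numpy(dtype=float)
        if np.ptp(x) > 0:  # constant covariates are dropped
            cols.append(x)
            names.append(cov)
    if with_interaction:
        age = frame["age"].to_numpy(dtype=float)
        cols.append(female * (age - age.mean()))
        names.append("female_x_age")
    design = np.column_stack(cols)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValidationError(f"rank-deficient design; columns: {names}")
    return design


def _term_f_test(y: np.ndarray, design: np.ndarray, col: int) -> tuple[float, float, float]:
    """F, p and coefficient for one single-df term of an OLS fit."""
    n, p = design.shape
    coef, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    df_resid = n - p
    if df_resid < 1:
        raise ValidationError("not enough subjects for the model")
    sigma2 = resid @ resid / df_resid
    scale = float(np.mean(y * y)) or 1.0
    if sigma2 <= 1e-24 * scale:  # numerically perfect fit
        if coef[col] ** 2 > 1e-20 * scale:
            return (float("inf"), 0.0, float(coef[col]))
        return (0.0, 1.0, float(coef[col]))
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(sigma2 * xtx_inv[col, col])
    tval = coef[col] / se
    fval = tval**2
    pval = stats.f.sf(fval, 1, df_resid)
    return (float(fval), float(pval), float(coef[col]))


def bonferroni(p_values, n_tests: int):
    """Multiply by the family size, cap at 1."""
    arr = np.atleast_1d(np.asarray(p_values, dtype=float))
    if ((arr < 0) | (arr > 1)).any():
        raise ValidationError("p-values must lie in [0, 1]")
    if n_tests < len(arr):
        raise ValidationError("family size smaller than number of tests")
    out = np.minimum(arr * n_tests, 1.0)
    return out if np.ndim(p_values) else float(out[0])


def sex_contrast(
    metrics: pd.DataFrame,
    cohort: Cohort,
    scope: str,
    metric: str = "temporal_clustering",
    n_tests: int = 2,
) -> SexContrastResult:
    """Between-subject sex effect from the split-plot ANCOVA.

    ``metrics`` must already be run-averaged. The female - male contrast
    direction is the sign of the adjusted sex coefficient.
    """
    frame = _subject_density_means(metrics, cohort, scope, metric)
    sexes = set(frame["sex"])
    if sexes != {"female", "male"}:
        raise ValidationError(f"need both sexes in the cohort, got {sexes}")
    if (frame["sex"] == "female").sum() < 2 or (frame["sex"] == "male").sum() < 2:
        raise ValidationError("need at least 2 subjects per sex")
    design = _design(frame)
    fval, pval, coef = _term_f_test(frame["y"].to_numpy(), design, col=1)
    return SexContrastResult(
        scope=scope,
        metric_name=metric,
        F=fval,
        p_uncorrected=pval,
        p_corrected=bonferroni(pval, n_tests),
        direction=int(np.sign(coef)),
        n_tests=n_tests,
    )


def interaction_screen(
    metrics: pd.DataFrame,
    cohort: Cohort,
    scope: str,
    metric: str = "temporal_clustering",
    n_tests: int = 2,
) -> float:
    """Corrected p of a sex-by-age interaction term (screen, not abort)."""
    frame = _subject_density_means(metrics, cohort, scope, metric)
    design = _design(frame, with_interaction=True)
    _, pval, _ = _term_f_test(frame["y"].to_numpy(), design, col=design.shape[1] - 1)
    return bonferroni(pval, n_tests)


def _rank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def partial_spearman(
    y: np.ndarray, x: np.ndarray, covariates: np.ndarray | None
) -> tuple[float, float]:
    """Partial Spearman rho of y with x given covariates, with t-test p.

    All inputs are mid-rank transformed; x and y ranks are residualized on
    the covariate ranks (constant covariates dropped); p uses
    n - 2 - (#covariates) degrees of freedom.
    """
    n = len(y)
    ry, rx = _rank(y), _rank(x)
    n_cov = 0
    if covariates is not None and covariates.size:
        kept = [c for c in covariates.T if np.ptp(c) > 0]
        n_cov = len(kept)
        if n_cov:
            z = np.column_stack(
                [np.ones(n)] + [_rank(c) for c in kept]
            )
            ry = ry - z @ np.linalg.lstsq(z, ry, rcond=None)[0]
            rx = rx - z @ np.linalg.lstsq(z, rx, rcond=None)[0]
    if n_cov == 0:
        rho = float(stats.spearmanr(y, x).statistic)
    else:
        rho = float(np.corrcoef(ry, rx)[0, 1])
    df = n - 2 - n_cov
    if df < 1:
        raise ValidationError("not enough subjects for the partial correlation")
    if abs(rho) >= 1.0:
        return (rho, 0.0)
    tval = rho * np.sqrt(df / (1 - rho**2))
    return (rho, float(2 * stats.t.sf(abs(tval), df)))


def age_correlation(
    metrics: pd.DataFrame,
    cohort: Cohort,
    scope: str,
    metric: str = "temporal_clustering",
    n_tests: int = 2,
) -> AgeCorrelationResult:
    """Partial Spearman of the density-averaged metric with age."""
    frame = _subject_density_means(metrics, cohort, scope, metric)
    age = frame["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        raise ValidationError("age is constant; correlation undefined")
    covariates = np.column_stack(
        [
            (frame["sex"] == "female").to_numpy(dtype=float),
            frame["education"].to_numpy(dtype=float),
            frame["mean_fd"].to_numpy(dtype=float),
        ]
    )
    rho, pval = partial_spearman(frame["y"].to_numpy(), age, covariates)
    return AgeCorrelationResult(
        scope=scope,
        metric_name=metric,
        rho=rho,
        p_uncorrected=pval,
        p_corrected=bonferroni(pval, n_tests),
        n_tests=n_tests,
    )
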