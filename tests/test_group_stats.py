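import numpy as np
import pandas as pd
import pytest
from scipy import stats

from temponet.group_stats import (
    age_correlation,
    average_runs,
    bonferroni,
    interaction_screen,
    partial_spearman,
    sex_contrast,
)
from temponet.io_core import Cohort, Subject, ValidationError


def metric_rows(subject, values_by_density, run="run1"):
    return [
        {
            "subject": subject,
            "run": run,
            "density": d,
            "scope": "global",
            "metric": "temporal_clustering",
            "value": v,
        }
        for d, v in values_by_density.items()
    ]


def cohort_from(records):
    return Cohort(
        subjects=tuple(Subject(**rec) for rec in records)
    )


class TestAverageRuns:
    def test_two_run_mean_and_single_run_identity(self):
        rows = metric_rows("s1", {0.1: 0.2}, run="run1") + metric_rows(
            "s1", {0.1: 0.4}, run="run2"
        )
        table = pd.DataFrame(rows)
        out = average_runs(table)
        assert out["value"].iloc[0] == pytest.approx(0.3)
        assert (out["run"] == "mean-of-runs").all()

        single = pd.DataFrame(metric_rows("s1", {0.1: 0.7}))
        assert average_runs(single)["value"].iloc[0] == pytest.approx(0.7)

    def test_run_order_irrelevant(self):
        rows = metric_rows("s1", {0.1: 0.2}, "run1") + metric_rows("s1", {0.1: 0.4}, "run2")
        fwd = average_runs(pd.DataFrame(rows))
        rev = average_runs(pd.DataFrame(rows[::-1]))
        pd.testing.assert_frame_equal(
            fwd.sort_index(axis=1), rev.sort_index(axis=1)
        )

    def test_unbalanced_runs_rejected(self):
        rows = (
            metric_rows("s1", {0.1: 0.2}, "run1")
            + metric_rows("s1", {0.1: 0.4}, "run2")
            + metric_rows("s2", {0.1: 0.3}, "run1")
        )
        with pytest.raises(ValidationError, match="unbalanced"):
            average_runs(pd.DataFrame(rows))


def toy_cohort(values, sexes, ages=None, edu=None, fd=None):
    n = len(values)
    ages = ages if ages is not None else [30.0] * n
    edu = edu if edu is not None else [15.0] * n
    fd = fd if fd is not None else [0.2] * n
    cohort = cohort_from(
        [
            dict(subject_id=f"s{i}", sex=sexes[i], age=ages[i],
                 education=edu[i], mean_fd=fd[i], run_paths=("r.tsv",))
            for i in range(n)
        ]
    )
    rows = []
    for i, v in enumerate(values):
        rows += metric_rows(f"s{i}", {0.1: v}, run="mean-of-runs")
    return pd.DataFrame(rows), cohort


class TestSexContrast:
    def test_reduces_to_one_way_anova_with_constant_covariates(self):
        # 6 subjects, covariates constant -> ANCOVA collapses to the
        # two-sample pooled-variance F = t^2
        female = [0.52, 0.55, 0.58]
        male = [0.41, 0.44, 0.46]
        table, cohort = toy_cohort(
            female + male, ["female"] * 3 + ["male"] * 3
        )
        res = sex_contrast(table, cohort, scope="global", n_tests=2)
        t_ref = stats.ttest_ind(female, male)
        assert res.F == pytest.approx(t_ref.statistic**2, abs=1e-10)
        assert res.p_uncorrected == pytest.approx(t_ref.pvalue, abs=1e-10)
        assert res.p_corrected == pytest.approx(min(1, 2 * t_ref.pvalue))
        assert res.direction == 1  # female > male

    def test_cloned_groups_give_null_f(self):
        values = [0.3, 0.4, 0.5, 0.3, 0.4, 0.5]
        table, cohort = toy_cohort(
            values, ["female", "female", "female", "male", "male", "male"],
            ages=[25, 30, 35, 25, 30, 35],
        )
        res = sex_contrast(table, cohort, scope="global")
        assert res.F == pytest.approx(0.0, abs=1e-20)
        assert res.p_uncorrected == pytest.approx(1.0)

    def test_affine_invariance(self, rng):
        values = rng.uniform(0.2, 0.8, size=12).tolist()
        sexes = ["female"] * 6 + ["male"] * 6
        ages = rng.uniform(22, 37, size=12).tolist()
        table, cohort = toy_cohort(values, sexes, ages=ages)
        base = sex_contrast(table, cohort, scope="global")
        scaled_table = table.copy()
        scaled_table["value"] = 100 * scaled_table["value"]  # affine metric
        res = sex_contrast(scaled_table, cohort, scope="global")
        assert res.F == pytest.approx(base.F, rel=1e-9)

    def test_one_sex_cohort_rejected(self):
        table, cohort = toy_cohort([0.1, 0.2, 0.3], ["female"] * 3)
        with pytest.raises(ValidationError, match="both sexes"):
            sex_contrast(table, cohort, scope="global")

    def test_collinear_covariates_rejected(self):
        table, cohort = toy_cohort(
            [0.1, 0.2, 0.3, 0.4, 0.5, 0.6],
            ["female"] * 3 + ["male"] * 3,
            ages=[25, 26, 27, 30, 31, 32],
            edu=[12.5, 13, 13.5, 15, 15.5, 16],  # education = age/2
        )
        with pytest.raises(ValidationError, match="rank-deficient"):
            sex_contrast(table, cohort, scope="global")


class TestPartialSpearman:
    def test_matches_explicit_residualization_oracle(self, rng):
        y = rng.normal(size=8)
        x = rng.normal(size=8)
        cov = rng.normal(size=(8, 2))
        rho, _ = partial_spearman(y, x, cov)

        def ranks(v):
            return stats.rankdata(v)

        z = np.column_stack([np.ones(8), ranks(cov[:, 0]), ranks(cov[:, 1])])
        ry = ranks(y) - z @ np.linalg.lstsq(z, ranks(y), rcond=None)[0]
        rx = ranks(x) - z @ np.linalg.lstsq(z, ranks(x), rcond=None)[0]
        oracle = np.corrcoef(ry, rx)[0, 1]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        y = rng.normal(size=30)
        x = 0.5 * y + rng.normal(size=30)
        cov = rng.normal(size=(30, 2))
        rho, p = partial_spearman(y, x, cov)
        frame = pd.DataFrame(
            {"y": y, "x": x, "c1": cov[:, 0], "c2": cov[:, 1]}
        )
        ref = pg.partial_corr(frame, "y", "x", covar=["c1", "c2"], method="spearman")
        assert rho == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)

    def test_constant_covariates_reduce_to_plain_spearman(self, rng):
        y = rng.normal(size=20)
        x = rng.normal(size=20)
        cov = np.full((20, 2), 3.0)
        rho, _ = partial_spearman(y, x, cov)
        assert rho == pytest.approx(stats.spearmanr(y, x).statistic, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        y = rng.normal(size=25)
        x = rng.normal(size=25)
        cov = rng.normal(size=(25, 1))
        base, _ = partial_spearman(y, x, cov)
        rho, _ = partial_spearman(np.exp(y), x**3, np.tanh(cov))
        assert rho == pytest.approx(base, abs=1e-12)


class TestAgeCorrelation:
    def test_recovers_strong_age_effect(self, rng):
        n = 100
        ages = rng.uniform(22, 37, size=n)
        values = 0.01 * ages + 0.001 * rng.normal(size=n)
        table, cohort = toy_cohort(
            values.tolist(),
            ["female" if i % 2 else "male" for i in range(n)],
            ages=ages.tolist(),
            edu=rng.normal(15, 2, size=n).tolist(),
            fd=np.abs(rng.normal(0.2, 0.05, size=n)).tolist(),
        )
        res = age_correlation(table, cohort, scope="global")
        assert res.rho > 0.9
        assert res.p_corrected < 0.01

    def test_constant_age_rejected(self):
        table, cohort = toy_cohort([0.1, 0.2, 0.3, 0.4],
                                   ["female", "male"] * 2)
        with pytest.raises(ValidationError, match="constant"):
            age_correlation(table, cohort, scope="global")


class TestBonferroni:
    @pytest.mark.parametrize(
        "p, n, expected",
        [(0.01, 18, 0.18), (0.2, 18, 1.0), (0.05, 1, 0.05)],
    )
    def test_arithmetic(self, p, n, expected):
        assert bonferroni(p, n) == pytest.approx(expected)

    def test_rejects_invalid_p(self):
        with pytest.raises(ValidationError):
            bonferroni([1.2], 2)
        with pytest.raises(ValidationError, match="family size"):
            bonferroni([0.1, 0.2, 0.3], 2)


class TestInteractionScreen:
    def test_cloned_groups_near_one(self):
        values = [0.3, 0.4, 0.5, 0.35, 0.3, 0.4, 0.5, 0.35]
        table, cohort = toy_cohort(
            values,
            ["female"] * 4 + ["male"] * 4,
            ages=[25, 28, 31, 34] * 2,
        )
        p = interaction_screen(table, cohort, scope="global", n_tests=1)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_built_in_interaction_detected(self, rng):
        n = 200
        ages = rng.uniform(22, 37, size=n)
        sexes = ["female" if i < n // 2 else "male" for i in range(n)]
        female = np.array([s == "female" for s in sexes])
        values = 0.02 * ages * female + 0.005 * rng.normal(size=n)
        table, cohort = toy_cohort(
            values.tolist(), sexes, ages=ages.tolist(),
            edu=rng.normal(15, 2, size=n).tolist(),
        )
        p = interaction_screen(table, cohort, scope="global", n_tests=2)
        assert p < 0.05
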