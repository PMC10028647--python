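"""Domain types and file I/O for the dynamic-network pipeline.

All pipeline inputs and outputs are plain delimited text: ROI time series
as TSV/CSV matrices (timepoints x nodes), parcellations as TSV membership
tables, cohort manifests as CSV, and metric/ICC/statistics tables as
long-form TSV. Node order is defined by the parcellation and must match
the column order of every time-series file.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: The nine functional subsystems used for subnetwork-level aggregation.
DEFAULT_SUBNETWORKS: tuple[str, ...] = (
    "default-mode",
    "salience",
    "visual",
    "subcortical",
    "auditory",
    "frontoparietal",
    "cinguloopercular",
    "sensorimotor",
    "attention",
)

#: Columns of the long-form metric table, in stable output order.
METRIC_COLUMNS: tuple[str, ...] = (
    "subject",
    "run",
    "density",
    "scope",
    "metric",
    "value",
)


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates a contract."""


@dataclass(frozen=True)
class RoiTimeSeries:
    """One run's ROI signal matrix.

    Parameters
    ----------
    subject_id, run_id
        Identifiers linking the run to the cohort manifest.
    data
        Array of shape (T, N): T timepoints by N nodes, float.
    tr_seconds
        Repetition time (sampling interval) in seconds.
    """

    subject_id: str
    run_id: str
    data: np.ndarray
    tr_seconds: float

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim != 2:
            raise ValidationError("time series must be a 2-D matrix")
        t, n = data.shape
        if t < 2 or n < 2:
            raise ValidationError(f"need T >= 2 and N >= 2, got T={t}, N={n}")
        if not np.isfinite(data).all():
            raise ValidationError("time series contains non-finite values")
        if self.tr_seconds <= 0:
            raise ValidationError("tr_seconds must be positive")
        variances = data.var(axis=0)
        dead = np.flatnonzero(variances == 0)
        if dead.size:
            raise ValidationError(
                f"zero-variance column(s) at 0-based index {dead.tolist()}"
            )

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.data.shape[1]


@dataclass(frozen=True)
class Parcellation:
    """Ordered node list with subnetwork membership.

    ``node_ids`` fixes the canonical node order for every downstream
    matrix; ``subnetwork_of`` maps each node id to exactly one subnetwork
    drawn from ``subnetwork_set``.
    """

    node_ids: tuple[str, ...]
    node_labels: tuple[str, ...]
    subnetwork_of: Mapping[str, str]
    subnetwork_set: tuple[str, ...] = DEFAULT_SUBNETWORKS

    def __post_init__(self) -> None:
        if len(self.node_ids) != len(set(self.node_ids)):
            raise ValidationError("duplicate node ids in parcellation")
        if len(self.node_labels) != len(self.node_ids):
            raise ValidationError("node_labels length must match node_ids")
        allowed = set(self.subnetwork_set)
        for node in self.node_ids:
            sub = self.subnetwork_of.get(node)
            if sub is None:
                raise ValidationError(f"node {node!r} has no subnetwork")
            if sub not in allowed:
                raise ValidationError(
                    f"node {node!r} maps to unknown subnetwork {sub!r}; "
                    f"declare it in the subnetwork set"
                )

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def members(self, subnetwork: str) -> list[int]:
        """0-based node indices belonging to one subnetwork."""
        return [
            i
            for i, node in enumerate(self.node_ids)
            if self.subnetwork_of[node] == subnetwork
        ]

    def present_subnetworks(self) -> list[str]:
        """Subnetworks with at least one member node, in declared order."""
        present = {self.subnetwork_of[n] for n in self.node_ids}
        return [s for s in self.subnetwork_set if s in present]


@dataclass(frozen=True)
class Subject:
    subject_id: str
    sex: str  # "female" or "male"
    age: float  # years
    education: float  # years
    mean_fd: float  # mean framewise displacement, mm
    run_paths: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.sex not in ("female", "male"):
            raise ValidationError(f"sex must be female/male, got {self.sex!r}")
        if self.mean_fd < 0:
            raise ValidationError("mean_fd must be nonnegative")


@dataclass(frozen=True)
class Cohort:
    """Subjects with covariates and per-run time-series references."""

    subjects: tuple[Subject, ...]

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(ids) != len(set(ids)):
            raise ValidationError("duplicate subject ids in cohort")
        k = {len(s.run_paths) for s in self.subjects}
        if len(k) > 1:
            raise ValidationError("all subjects must have the same number of runs")

    @property
    def n_runs(self) -> int:
        return len(self.subjects[0].run_paths) if self.subjects else 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subject": [s.subject_id for s in self.subjects],
                "sex": [s.sex for s in self.subjects],
                "age": [s.age for s in self.subjects],
                "education": [s.education for s in self.subjects],
                "mean_fd": [s.mean_fd for s in self.subjects],
            }
        )


# ---------------------------------------------------------------------------
# readers / writers


def read_timeseries(
    path: str | Path,
    tr_seconds: float,
    subject_id: str = "",
    run_id: str = "",
) -> RoiTimeSeries:
    """Read a T x N delimited time-series matrix.

    Accepts TSV or CSV (sniffed from the extension, default tab), with an
    optional header row of node ids. Raises :class:`ValidationError` on
    non-numeric cells, ragged rows, or zero-variance columns, naming the
    offending row or column.
    """
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    with open(path) as fh:
        first = fh.readline()
    tokens = first.strip().split(sep)

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    # a header row is all node ids; a mixed row is malformed data
    has_header = tokens and not any(_is_number(t) for t in tokens)
    try:
        frame = pd.read_csv(
            path,
            sep=sep,
            header=0 if has_header else None,
            float_precision="round_trip",
        )
    except pd.errors.ParserError as exc:
        raise ValidationError(f"ragged or malformed rows in {path}: {exc}") from exc
    bad = frame.columns[frame.dtypes == object]
    if len(bad):
        for col in bad:
            row = frame[pd.to_numeric(frame[col], errors="coerce").isna()].index
            raise ValidationError(
                f"non-numeric cell in column {col!r}, data row {row[0]} of {path}"
            )
    data = frame.to_numpy(dtype=float)
    if np.isnan(data).any():
        r, c = np.argwhere(np.isnan(data))[0]
        raise ValidationError(f"missing value at row {r}, column {c} of {path}")
    return RoiTimeSeries(
        subject_id=subject_id or path.stem,
        run_id=run_id or "run1",
        data=data,
        tr_seconds=tr_seconds,
    )


def write_timeseries(ts: RoiTimeSeries, path: str | Path) -> None:
    """Write the matrix as headerless TSV at full float precision."""
    np.savetxt(path, ts.data, delimiter="\t", fmt="%.17g")


def read_parcellation(
    path: str | Path,
    subnetwork_set: Sequence[str] | None = None,
) -> Parcellation:
    """Read a TSV with columns node_id, label, subnetwork.

    A custom ``subnetwork_set`` (e.g. from config) permits names outside
    the default nine.
    """
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"node_id", "label", "subnetwork"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"parcellation needs columns {sorted(required)}")
    if frame["node_id"].duplicated().any():
        dups = frame.loc[frame["node_id"].duplicated(), "node_id"].tolist()
        raise ValidationError(f"duplicate node ids: {dups}")
    if frame["subnetwork"].isna().any():
        missing = frame.loc[frame["subnetwork"].isna(), "node_id"].tolist()
        raise ValidationError(f"nodes missing a subnetwork: {missing}")
    return Parcellation(
        node_ids=tuple(frame["node_id"]),
        node_labels=tuple(frame["label"]),
        subnetwork_of=dict(zip(frame["node_id"], frame["subnetwork"])),
        subnetwork_set=tuple(subnetwork_set) if subnetwork_set else DEFAULT_SUBNETWORKS,
    )


def write_parcellation(parc: Parcellation, path: str | Path) -> None:
    pd.DataFrame(
        {
            "node_id": parc.node_ids,
            "label": parc.node_labels,
            "subnetwork": [parc.subnetwork_of[n] for n in parc.node_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort manifest CSV (subject_id, sex, age, education, mean_fd, run1..runk)."""
    frame = pd.read_csv(path)
    run_cols = sorted(
        (c for c in frame.columns if c.startswith("run")),
        key=lambda c: int(c[3:]),
    )
    subjects = tuple(
        Subject(
            subject_id=str(row["subject_id"]),
            sex=str(row["sex"]),
            age=float(row["age"]),
            education=float(row["education"]),
            mean_fd=float(row["mean_fd"]),
            run_paths=tuple(str(row[c]) for c in run_cols),
        )
        for _, row in frame.iterrows()
    )
    return Cohort(subjects=subjects)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    frame = cohort.to_frame().rename(columns={"subject": "subject_id"})
    for j in range(cohort.n_runs):
        frame[f"run{j + 1}"] = [s.run_paths[j] for s in cohort.subjects]
    frame.to_csv(path, index=False)


def validate_metric_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the long-form metric table contract and return it.

    Columns (subject, run, density, scope, metric, value); bounded metrics
    lie in [0, 1]; the (subject, run, density, scope, metric) key is unique.
    """
    missing = set(METRIC_COLUMNS) - set(table.columns)
    if missing:
        raise ValidationError(f"metric table missing columns {sorted(missing)}")
    key = list(METRIC_COLUMNS[:-1])
    if table.duplicated(subset=key).any():
        raise ValidationError("duplicate (subject, run, density, scope, metric) keys")
    bounded = table["metric"].isin(
        ["temporal_clustering", "clustering", "local_efficiency"]
    )
    vals = table.loc[bounded, "value"]
    if len(vals) and ((vals < -1e-12) | (vals > 1 + 1e-12)).any():
        raise ValidationError("bounded metric value outside [0, 1]")
    return table[list(METRIC_COLUMNS)]


def write_metric_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a long-form metric TSV with stable columns and full precision."""
    validate_metric_table(table).to_csv(
        path, sep="\t", index=False, float_format="%.17g"
    )


def read_metric_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(
        path,
        sep="\t",
        dtype={"subject": str, "run": str, "scope": str, "metric": str},
        float_precision="round_trip",
    )
    if table.empty:  # header-only file: enforce dtypes
        table = table.astype({"density": float, "value": float})
    return validate_metric_table(table)


def write_run_metadata(path: str | Path, **params) -> None:
    """JSON sidecar recording parameters and seed for provenance."""
    with open(path, "w") as fh:
        json.dump(params, fh, indent=2, sort_keys=True, default=str)
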