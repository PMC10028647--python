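"""Temporal clustering coefficients on binary multilayer networks.

The nodal temporal clustering coefficient of node i measures how
consistently i keeps the same neighbors across consecutive layers:

    C_i = (1/(T-1)) * sum_{t=1}^{T-1}
          sum_j a_ij(t) a_ij(t+1) / sqrt(sum_j a_ij(t) * sum_j a_ij(t+1))

where a_ij(t) is the binary adjacency of layer t and T the number of
layers. The numerator counts neighbors retained from layer t to t+1; the
denominator is the geometric mean of the two degrees, so each term lies in
[0, 1] by Cauchy-Schwarz. Transitions where node i is isolated in either
layer contribute 0 (the 0/0 convention; the divisor stays T-1), which
keeps the coefficient defined at very low densities.

Global and subnetwork coefficients are unweighted means of the nodal
values over all nodes, respectively over the member nodes of each
subnetwork.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .dynet import DEFAULT_DENSITY_GRID, MultilayerNetwork, WindowSpec, build_multilayer
from .io_core import (
    METRIC_COLUMNS,
    Parcellation,
    RoiTimeSeries,
    ValidationError,
    validate_metric_table,
)


@dataclass(frozen=True)
class TemporalClusteringResult:
    nodal: np.ndarray
    global_value: float
    subnetwork_values: Mapping[str, float]


def nodal_temporal_clustering(net: MultilayerNetwork) -> np.ndarray:
    """Per-node temporal clustering coefficient, vectorized over layers."""
    layers = net.layers
    if layers.shape[0] < 2:
        raise ValidationError("temporal clustering needs at least 2 layers")
    a, b = layers[:-1], layers[1:]
    overlap = (a & b).sum(axis=2).astype(float)  # (T-1, N)
    deg_prod = a.sum(axis=2) * b.sum(axis=2)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(deg_prod > 0, overlap / np.sqrt(deg_prod), 0.0)
    return terms.mean(axis=0)


def aggregate_temporal_clustering(
    nodal: np.ndarray, parcellation: Parcellation
) -> TemporalClusteringResult:
    """Global and per-subnetwork unweighted means of nodal values."""
    if len(nodal) != parcellation.n_nodes:
        raise ValidationError(
            f"nodal vector length {len(nodal)} != parcellation size "
            f"{parcellation.n_nodes}"
        )
    sub_values = {
        sub: float(np.mean(nodal[parcellation.members(sub)]))
        for sub in parcellation.present_subnetworks()
    }
    return TemporalClusteringResult(
        nodal=np.asarray(nodal, dtype=float),
        global_value=float(np.mean(nodal)),
        subnetwork_values=sub_values,
    )


def result_records(
    result_nodal: np.ndarray,
    parcellation: Parcellation,
    subject_id: str,
    run_id: str,
    density: float,
    metric: str,
) -> list[dict]:
    """Long-form records at global, subnetwork and node scopes."""
    agg = aggregate_temporal_clustering(result_nodal, parcellation)
    rows = [
        {
            "subject": subject_id,
            "run": run_id,
            "density": density,
            "scope": "global",
            "metric": metric,
            "value": agg.global_value,
        }
    ]
    rows += [
        {
            "subject": subject_id,
            "run": run_id,
            "density": density,
            "scope": f"subnetwork:{sub}",
            "metric": metric,
            "value": val,
        }
        for sub, val in agg.subnetwork_values.items()
    ]
    rows += [
        {
            "subject": subject_id,
            "run": run_id,
            "density": density,
            "scope": f"node:{node}",
            "metric": metric,
            "value": float(v),
        }
        for node, v in zip(parcellation.node_ids, result_nodal)
    ]
    return rows


def run_temporal_pipeline(
    ts: RoiTimeSeries,
    spec: WindowSpec,
    density_grid: tuple[float, ...] = DEFAULT_DENSITY_GRID,
    parcellation: Parcellation | None = None,
    rank_by: str = "signed",
) -> pd.DataFrame:
    """Sliding windows -> thresholded stacks -> temporal clustering table.

    Returns a long-form metric table with metric_name "temporal_clustering"
    at global, subnetwork and node scopes for every density in the grid.
    """
    if parcellation is None:
        raise ValidationError("run_temporal_pipeline requires a parcellation")
    nets = build_multilayer(ts, spec, density_grid, rank_by)
    rows: list[dict] = []
    for density, net in nets.items():
        nodal = nodal_temporal_clustering(net)
        rows += result_records(
            nodal, parcellation, ts.subject_id, ts.run_id, density,
            "temporal_clustering",
        )
    return validate_metric_table(pd.DataFrame(rows, columns=METRIC_COLUMNS))
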