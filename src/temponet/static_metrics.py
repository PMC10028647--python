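"""Static comparator metrics: binary clustering coefficient and local efficiency.

The static network for a run is the Pearson correlation of the whole scan,
proportionally thresholded with the same rules as the windowed networks.
Both metrics follow the standard binary conventions: clustering is
2*t_i / (k_i (k_i - 1)) with t_i the triangle count through node i, and
local efficiency is the average inverse shortest-path length among node
i's neighbors within the subgraph they induce (unreachable pairs
contribute 0); both are 0 for nodes of degree < 2. Graph machinery is
delegated to networkx.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .dynet import DEFAULT_DENSITY_GRID, threshold_proportional
from .io_core import (
    METRIC_COLUMNS,
    Parcellation,
    RoiTimeSeries,
    validate_metric_table,
)
from .temporal_metrics import result_records


@dataclass(frozen=True)
class StaticNetwork:
    adjacency: np.ndarray  # binary symmetric, zero diagonal
    density: float

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]


def build_static(
    ts: RoiTimeSeries, density: float, rank_by: str = "signed"
) -> StaticNetwork:
    """Full-run Pearson correlation, proportionally thresholded."""
    corr = np.corrcoef(ts.data, rowvar=False)
    return StaticNetwork(
        adjacency=threshold_proportional(corr, density, rank_by), density=density
    )


def static_clustering(net: StaticNetwork) -> np.ndarray:
    graph = nx.from_numpy_array(net.adjacency)
    cc = nx.clustering(graph)
    return np.array([cc[i] for i in range(net.n_nodes)], dtype=float)


def local_efficiency(net: StaticNetwork) -> np.ndarray:
    """Nodal local efficiency with neighbor-subgraph distances."""
    graph = nx.from_numpy_array(net.adjacency)
    out = np.zeros(net.n_nodes)
    for i in range(net.n_nodes):
        neighbors = list(graph[i])
        if len(neighbors) < 2:
            continue
        # global_efficiency averages 1/d over ordered pairs of the induced
        # subgraph, i.e. divides by k_i (k_i - 1); unreachable pairs add 0.
        out[i] = nx.global_efficiency(graph.subgraph(neighbors))
    return out


def run_static_pipeline(
    ts: RoiTimeSeries,
    density_grid: tuple[float, ...] = DEFAULT_DENSITY_GRID,
    parcellation: Parcellation | None = None,
    rank_by: str = "signed",
) -> pd.DataFrame:
    """Metric table for "clustering" and "local_efficiency" at all scopes."""
    if parcellation is None:
        raise ValueError("run_static_pipeline requires a parcellation")
    rows: list[dict] = []
    for density in density_grid:
        net = build_static(ts, density, rank_by)
        rows += result_records(
            static_clustering(net), parcellation, ts.subject_id, ts.run_id,
            density, "clustering",
        )
        rows += result_records(
            local_efficiency(net), parcellation, ts.subject_id, ts.run_id,
            density, "local_efficiency",
        )
    return validate_metric_table(pd.DataFrame(rows, columns=METRIC_COLUMNS))
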