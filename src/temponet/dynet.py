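"""Sliding-window dynamic network construction.

A run's T x N signal matrix is segmented into overlapping rectangular
windows; within each window the N x N Pearson correlation matrix is
computed; each window's matrix is then binarized by proportional
thresholding (keep the top fraction ``density`` of the N(N-1)/2 possible
edges) to give one binary layer of a multilayer network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import RoiTimeSeries, ValidationError

#: 1% to 50% in 1% steps: the default density sweep (50 levels).
DEFAULT_DENSITY_GRID: tuple[float, ...] = tuple(
    round(0.01 * d, 2) for d in range(1, 51)
)


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry in TR units."""

    width_tr: int
    step_tr: int

    def __post_init__(self) -> None:
        if self.width_tr < 2:
            raise ValidationError("window width must be at least 2 TRs")
        if self.step_tr < 1:
            raise ValidationError("step must be at least 1 TR")

    def width_seconds(self, tr_seconds: float) -> float:
        return self.width_tr * tr_seconds

    def step_seconds(self, tr_seconds: float) -> float:
        return self.step_tr * tr_seconds


@dataclass(frozen=True)
class CorrelationStack:
    """W real symmetric N x N Pearson matrices, one per window."""

    layers: np.ndarray  # (W, N, N)
    window_starts: tuple[int, ...]

    @property
    def n_windows(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


@dataclass(frozen=True)
class MultilayerNetwork:
    """Ordered stack of binary symmetric adjacency layers at one density."""

    layers: np.ndarray  # (W, N, N) of 0/1, zero diagonal
    density: float

    @property
    def n_windows(self) -> int:
        return self.layers.shape[0]

    @property
    def n_nodes(self) -> int:
        return self.layers.shape[1]


def plan_windows(t_points: int, spec: WindowSpec) -> list[tuple[int, int]]:
    """Half-open 0-based window intervals [s, s + width).

    Starts run 0, step, 2*step, ...; the count is
    floor((T - width)/step) + 1 and trailing timepoints not covered by a
    full window are discarded.
    """
    if spec.width_tr > t_points:
        raise ValidationError(
            f"window width {spec.width_tr} exceeds series length {t_points}"
        )
    n_windows = (t_points - spec.width_tr) // spec.step_tr + 1
    return [
        (s, s + spec.width_tr)
        for s in range(0, n_windows * spec.step_tr, spec.step_tr)
    ]


def window_correlations(ts: RoiTimeSeries, spec: WindowSpec) -> CorrelationStack:
    """Pearson correlation matrix of every window segment."""
    windows = plan_windows(ts.n_timepoints, spec)
    n = ts.n_nodes
    layers = np.empty((len(windows), n, n))
    for w, (start, stop) in enumerate(windows):
        seg = ts.data[start:stop]
        sd = seg.std(axis=0)
        dead = np.flatnonzero(sd == 0)
        if dead.size:
            raise ValidationError(
                f"zero-variance node(s) {dead.tolist()} in window {w} "
                f"[{start}, {stop})"
            )
        layers[w] = np.corrcoef(seg, rowvar=False)
    return CorrelationStack(layers=layers, window_starts=tuple(s for s, _ in windows))


def edge_count(density: float, n_nodes: int) -> int:
    """round(density * N(N-1)/2), rounding half away from zero."""
    x = density * n_nodes * (n_nodes - 1) / 2.0
    return int(np.floor(x + 0.5))


def _ranked_edges(corr: np.ndarray, rank_by: str) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle edges sorted by strength desc, ties by (i, j) asc."""
    iu, ju = np.triu_indices(corr.shape[0], k=1)
    vals = corr[iu, ju]
    if rank_by == "absolute":
        vals = np.abs(vals)
    elif rank_by != "signed":
        raise ValueError("rank_by must be 'signed' or 'absolute'")
    # lexsort: last key is primary. -vals gives descending strength;
    # (iu, ju) already enumerate ties in ascending lexicographic order and
    # lexsort is stable within equal primary keys via the earlier keys.
    order = np.lexsort((ju, iu, -vals))
    return iu[order], ju[order]


def threshold_proportional(
    corr: np.ndarray, density: float, rank_by: str = "signed"
) -> np.ndarray:
    """Binarize a symmetric matrix by keeping the strongest edges.

    Keeps the ``round(density * N(N-1)/2)`` upper-triangle entries with the
    largest signed correlation (or ``|r|`` when ``rank_by='absolute'``),
    symmetrizes, and zeroes the diagonal. Ties at the cutoff are broken by
    ascending (i, j) order, so the result is deterministic.
    """
    n = corr.shape[0]
    if not 0 < density <= 1:
        raise ValidationError("density must lie in (0, 1]")
    k = edge_count(density, n)
    adj = np.zeros((n, n), dtype=np.int8)
    if k == 0:
        warnings.warn(f"density {density} keeps zero edges at N={n}", stacklevel=2)
        return adj
    ei, ej = _ranked_edges(corr, rank_by)
    keep_i, keep_j = ei[:k], ej[:k]
    adj[keep_i, keep_j] = 1
    adj[keep_j, keep_i] = 1
    return adj


def threshold_stack(
    stack: CorrelationStack, density: float, rank_by: str = "signed"
) -> MultilayerNetwork:
    """Proportional-threshold every window layer at one density."""
    layers = np.stack(
        [threshold_proportional(stack.layers[w], density, rank_by) for w in range(stack.n_windows)]
    )
    return MultilayerNetwork(layers=layers, density=density)


def build_multilayer(
    ts: RoiTimeSeries,
    spec: WindowSpec,
    density_grid: tuple[float, ...] = DEFAULT_DENSITY_GRID,
    rank_by: str = "signed",
) -> dict[float, MultilayerNetwork]:
    """Window correlations once, then threshold at every density.

    Sorting each window's edges once and cutting at every density makes the
    full 50-level sweep no more expensive than a single threshold.
    """
    for d in density_grid:
        if not 0 < d <= 1:
            raise ValidationError(f"density {d} outside (0, 1]")
    stack = window_correlations(ts, spec)
    w_count, n = stack.n_windows, stack.n_nodes
    ks = {d: edge_count(d, n) for d in density_grid}
    out = {
        d: np.zeros((w_count, n, n), dtype=np.int8) for d in density_grid
    }
    for w in range(w_count):
        ei, ej = _ranked_edges(stack.layers[w], rank_by)
        for d, k in ks.items():
            if k == 0:
                warnings.warn(
                    f"density {d} keeps zero edges at N={n}", stacklevel=2
                )
                continue
            out[d][w][ei[:k], ej[:k]] = 1
            out[d][w][ej[:k], ei[:k]] = 1
    return {
        d: MultilayerNetwork(layers=layers, density=d) for d, layers in out.items()
    }
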