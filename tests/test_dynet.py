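import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from temponet.dynet import (
    DEFAULT_DENSITY_GRID,
    WindowSpec,
    build_multilayer,
    edge_count,
    plan_windows,
    threshold_proportional,
    window_correlations,
)
from temponet.io_core import RoiTimeSeries, ValidationError


class TestPlanWindows:
    @pytest.mark.parametrize(
        "t, width, step, expected_count",
        [
            (1200, 139, 8, 133),  # the full-scale geometry
            (139, 139, 8, 1),
            (20, 10, 5, 3),
        ],
    )
    def test_window_counts(self, t, width, step, expected_count):
        windows = plan_windows(t, WindowSpec(width, step))
        assert len(windows) == expected_count
        assert windows[0] == (0, width)
        starts = [s for s, _ in windows]
        assert starts == list(range(0, expected_count * step, step))
        assert all(e - s == width for s, e in windows)
        assert windows[-1][1] <= t  # trailing partial windows discarded

    def test_width_exceeding_series_rejected(self):
        with pytest.raises(ValidationError, match="exceeds"):
            plan_windows(100, WindowSpec(101, 8))

    @settings(derandomize=True, max_examples=200)
    @given(
        t=st.integers(2, 3000),
        width=st.integers(2, 3000),
        step=st.integers(1, 50),
    )
    def test_count_closed_form_matches_enumeration(self, t, width, step):
        if width > t:
            return
        windows = plan_windows(t, WindowSpec(width, step))
        brute = [s for s in range(0, t, step) if s + width <= t]
        assert len(windows) == (t - width) // step + 1 == len(brute)

    def test_window_seconds(self):
        spec = WindowSpec(139, 8)
        assert spec.width_seconds(0.72) == pytest.approx(100.08)
        assert spec.step_seconds(0.72) == pytest.approx(5.76)


class TestWindowCorrelations:
    def test_affine_copies_give_unit_correlation(self, rng):
        x = rng.normal(size=60)
        data = np.column_stack([x, 2.5 * x + 1.0, -x])
        ts = RoiTimeSeries("s", "r", data, 0.72)
        stack = window_correlations(ts, WindowSpec(20, 10))
        assert stack.n_windows == 5
        np.testing.assert_allclose(stack.layers[:, 0, 1], 1.0)
        np.testing.assert_allclose(stack.layers[:, 0, 2], -1.0)

    def test_matches_direct_pearson_formula(self):
        # 6-timepoint, 3-node toy evaluated against the formula by hand
        data = np.array(
            [
                [1.0, 2.0, 5.0],
                [2.0, 1.0, 4.0],
                [3.0, 4.0, 3.0],
                [4.0, 3.0, 3.0],
                [5.0, 6.0, 1.0],
                [6.0, 5.0, 0.0],
            ]
        )
        ts = RoiTimeSeries("s", "r", data, 0.72)
        stack = window_correlations(ts, WindowSpec(6, 1))
        def pearson(x, y):
            xc, yc = x - x.mean(), y - y.mean()
            return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
        expected = np.eye(3)
        for i in range(3):
            for j in range(i + 1, 3):
                expected[i, j] = expected[j, i] = pearson(data[:, i], data[:, j])
        np.testing.assert_allclose(stack.layers[0], expected, atol=1e-14)

    def test_zero_variance_window_names_node(self, rng):
        data = rng.normal(size=(40, 3))
        data[:20, 1] = 7.0  # constant only within the first window
        ts = RoiTimeSeries("s", "r", data, 0.72)
        with pytest.raises(ValidationError, match=r"\[1\] in window 0"):
            window_correlations(ts, WindowSpec(20, 10))


class TestThresholding:
    def test_keeps_largest_signed_values(self, rng):
        corr = np.zeros((4, 4))
        vals = {(0, 1): 0.9, (0, 2): -0.8, (0, 3): 0.5, (1, 2): 0.1, (1, 3): 0.7, (2, 3): 0.3}
        for (i, j), v in vals.items():
            corr[i, j] = corr[j, i] = v
        adj = threshold_proportional(corr, 0.5)
        assert adj.sum() // 2 == 3
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4) if adj[i, j]}
        assert kept == {(0, 1), (1, 3), (0, 3)}  # three largest signed r

    def test_absolute_ranking_flag(self):
        corr = np.zeros((3, 3))
        corr[0, 1] = corr[1, 0] = -0.9
        corr[0, 2] = corr[2, 0] = 0.5
        corr[1, 2] = corr[2, 1] = 0.1
        adj = threshold_proportional(corr, 1 / 3, rank_by="absolute")
        assert adj[0, 1] == 1 and adj.sum() == 2

    def test_tie_break_is_lexicographic(self):
        corr = np.full((4, 4), 0.5)
        np.fill_diagonal(corr, 1.0)
        adj = threshold_proportional(corr, 0.5)
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4) if adj[i, j]}
        assert kept == {(0, 1), (0, 2), (0, 3)}

    def test_full_density_gives_complete_graph(self, rng):
        corr = np.corrcoef(rng.normal(size=(30, 5)), rowvar=False)
        adj = threshold_proportional(corr, 1.0)
        assert adj.sum() == 5 * 4
        assert np.diag(adj).sum() == 0
        np.testing.assert_array_equal(adj, adj.T)

    def test_zero_edges_warns(self):
        corr = np.eye(3)
        with pytest.warns(UserWarning, match="zero edges"):
            adj = threshold_proportional(corr, 0.01)
        assert adj.sum() == 0

    @settings(derandomize=True, max_examples=100)
    @given(n=st.integers(3, 12), d=st.floats(0.05, 1.0))
    def test_edge_count_exact(self, n, d):
        rng = np.random.default_rng(n)
        corr = np.corrcoef(rng.normal(size=(3 * n, n)), rowvar=False)
        adj = threshold_proportional(corr, d)
        assert adj.sum() // 2 == edge_count(d, n)

    def test_invariant_to_monotone_transform(self, rng):
        corr = np.corrcoef(rng.normal(size=(50, 8)), rowvar=False)
        monotone = np.tanh(3 * corr) + 0.1 * corr  # strictly increasing
        for d in (0.1, 0.3, 0.5):
            np.testing.assert_array_equal(
                threshold_proportional(corr, d),
                threshold_proportional(monotone, d),
            )


class TestBuildMultilayer:
    def test_default_grid_yields_50_networks(self, rng):
        assert len(DEFAULT_DENSITY_GRID) == 50
        data = rng.normal(size=(60, 6))
        ts = RoiTimeSeries("s", "r", data, 0.72)
        nets = build_multilayer(ts, WindowSpec(20, 10))
        assert len(nets) == 50
        assert all(net.n_windows == 5 for net in nets.values())

    def test_density_nesting_per_layer(self, rng):
        data = rng.normal(size=(80, 7))
        ts = RoiTimeSeries("s", "r", data, 0.72)
        nets = build_multilayer(ts, WindowSpec(30, 10), (0.1, 0.3, 0.5))
        for lo, hi in [(0.1, 0.3), (0.3, 0.5)]:
            diff = nets[hi].layers - nets[lo].layers
            assert (diff >= 0).all()  # lower density is a subgraph

    def test_matches_single_threshold_path(self, rng):
        data = rng.normal(size=(50, 6))
        ts = RoiTimeSeries("s", "r", data, 0.72)
        nets = build_multilayer(ts, WindowSpec(25, 5), (0.2,))
        stack = window_correlations(ts, WindowSpec(25, 5))
        for w in range(stack.n_windows):
            np.testing.assert_array_equal(
                nets[0.2].layers[w], threshold_proportional(stack.layers[w], 0.2)
            )
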