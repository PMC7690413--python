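import numpy as np
import pandas as pd
import pytest

import riverdrift as rd
from riverdrift.network import (
    build_network,
    distance_trends,
    edges_frame,
    fr_layout,
    pearson_with_p,
    trend_classes,
)

from .oracles import pearson_oracle


class TestPearson:
    def test_perfect_positive_linearity(self):
        x = np.arange(10.0)
        res = pearson_with_p(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.p < 1e-15

    def test_sign_symmetry(self):
        x = np.arange(5.0)
        assert pearson_with_p(x, -x).r == pytest.approx(-1.0)

    def test_known_p_at_r_09_n_5(self):
        """Sample r = 0.9 with n = 5 gives two-sided p ~ 0.0374."""
        x = np.array([-2.0, -1.0, 0.0, 1.0, 2.0])
        z = np.array([1.0, -1.0, 0.0, -1.0, 1.0])  # orthogonal to x, mean 0
        xs = x / np.sqrt((x**2).sum())
        zs = z / np.sqrt((z**2).sum())
        y = 0.9 * xs + np.sqrt(1 - 0.81) * zs
        res = pearson_with_p(x, y)
        assert res.r == pytest.approx(0.9, abs=1e-12)
        assert res.p == pytest.approx(0.0374, abs=5e-4)

    def test_constant_series_distinct_error(self):
        with pytest.raises(rd.ConstantSeriesError):
            pearson_with_p([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_short_series_rejected(self):
        with pytest.raises(rd.ValidationError):
            pearson_with_p([1.0, 2.0], [1.0, 2.0])

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            res = pearson_with_p(x, y)
            r_o, p_o = pearson_oracle(x, y)
            assert res.r == pytest.approx(r_o, abs=1e-12)
            assert res.p == pytest.approx(p_o, abs=1e-10)


class TestDistanceTrends:
    def test_monotone_series_forced_classes(self):
        d = np.linspace(0, 11000, 20)
        frame = pd.DataFrame({"down": np.linspace(1, 0, 20), "up": np.linspace(0, 1, 20)})
        out = trend_classes(frame, d)
        assert out.loc["down", "trend"] == "decreasing"
        assert out.loc["up", "trend"] == "increasing"

    def test_constant_series_is_none_with_nan(self):
        d = np.linspace(0, 1, 10)
        out = trend_classes(pd.DataFrame({"c": np.ones(10)}), d)
        assert out.loc["c", "trend"] == "none"
        assert np.isnan(out.loc["c", "r"])

    def test_null_type_one_error_control(self):
        """i.i.d. noise: ~5% of 1000 variables called at alpha = 0.05."""
        rng = np.random.default_rng(2024)
        d = np.linspace(48, 11000, 20)
        frame = pd.DataFrame(rng.normal(size=(20, 1000)))
        frame.columns = [f"v{i}" for i in range(1000)]
        out = trend_classes(frame, d)
        frac = (out["trend"] != "none").mean()
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(frac - 0.05) <= 3 * se

    def test_decaying_otus_recovered_decreasing(self, default_run):
        out = distance_trends(default_run["subset"], default_run["metadata"])
        truth = default_run["truth"].labels
        decayers = [
            o for o in truth[truth.archetype == "lake_decaying"].index
            if o in out.index
        ]
        frac = np.mean([out.loc[o, "trend"] == "decreasing" for o in decayers])
        assert frac >= 0.9

    def test_env_parameters_classified(self, default_run):
        out = distance_trends(default_run["subset"], default_run["metadata"])
        assert out.loc["temperature_c", "trend"] == "decreasing"
        assert out.loc["turbidity_ntu", "trend"] == "increasing"
        assert out.loc["total_phosphorus_ug_per_l", "trend"] == "none"


class TestBuildNetwork:
    def test_identical_series_forced_edge(self):
        from .conftest import make_metadata

        from riverdrift.tables import ProportionTable

        meta = make_metadata([1000, 2000, 3000, 4000, 5000])
        rng = np.random.default_rng(0)
        base = rng.uniform(0.1, 0.4, size=6)
        props = ProportionTable(
            site_ids=meta.ordered_sites,
            otu_ids=["a", "b"],
            proportions=np.stack([base, base], axis=1) / 2,
            detected=np.ones((6, 2), bool),
            otu_totals=np.array([100.0, 100.0]),
        )
        g = build_network(props, meta, include_distance=False)
        assert g.has_edge("a", "b")
        assert g.edges["a", "b"]["r"] == pytest.approx(1.0)
        assert g.edges["a", "b"]["sign"] == 1

    def test_null_edge_density_near_alpha(self):
        from .conftest import make_metadata

        from riverdrift.tables import ProportionTable

        meta = make_metadata([float(d) for d in np.linspace(500, 11000, 20)])
        rng = np.random.default_rng(5)
        n_vars = 60
        mat = rng.uniform(0.001, 0.01, size=(21, n_vars))
        props = ProportionTable(
            site_ids=meta.ordered_sites,
            otu_ids=[f"o{i}" for i in range(n_vars)],
            proportions=mat,
            detected=mat > 0,
            otu_totals=mat.sum(axis=0),
        )
        g = build_network(props, meta, alpha=0.05, include_distance=False)
        density = g.number_of_edges() / (n_vars * (n_vars - 1) / 2)
        se = np.sqrt(0.05 * 0.95 / (n_vars * (n_vars - 1) / 2))
        assert abs(density - 0.05) <= 4 * se

    def test_edges_nested_in_alpha(self, default_run):
        strict = build_network(default_run["subset"], default_run["metadata"], alpha=0.001)
        loose = build_network(default_run["subset"], default_run["metadata"], alpha=0.01)
        assert set(strict.edges) <= set(loose.edges)

    def test_structural_recovery_two_clusters(self, default_run):
        """Decayers covary with temperature/TOC; risers oppose them."""
        g = build_network(default_run["subset"], default_run["metadata"], alpha=0.01)
        truth = default_run["truth"].labels
        decayers = [o for o in truth[truth.trend == "-"].index if g.has_node(o)]
        risers = [o for o in truth[truth.trend == "+"].index if g.has_node(o)]
        within = [
            g.edges[u, v]["sign"]
            for i, u in enumerate(decayers)
            for v in decayers[i + 1:]
            if g.has_edge(u, v)
        ]
        across = [
            g.edges[u, v]["sign"] for u in decayers for v in risers if g.has_edge(u, v)
        ]
        assert np.mean(within) > 0.8
        assert np.mean(across) < -0.8
        # temperature joins the decreasing cluster positively
        temp_edges = [
            g.edges["temperature_c", v]["sign"]
            for v in decayers
            if g.has_edge("temperature_c", v)
        ]
        assert temp_edges and np.mean(temp_edges) > 0.8

    def test_edges_frame_columns(self, default_run):
        g = build_network(default_run["subset"], default_run["metadata"])
        frame = edges_frame(g)
        assert list(frame.columns) == ["node_u", "node_v", "r", "p", "sign"]
        assert (frame["p"] < 0.01).all()


class TestLayout:
    def _pair_graph(self):
        import networkx as nx

        g = nx.Graph()
        for n in "abcd":
            g.add_node(n)
        g.add_edge("a", "b", weight=1.0, r=1.0, p=0.001, sign=1)
        return g

    def test_deterministic_given_seed(self):
        g = self._pair_graph()
        a = fr_layout(g, seed=3)
        b = fr_layout(g, seed=3)
        for n in g.nodes:
            np.testing.assert_array_equal(a[n], b[n])

    def test_connected_nodes_closer_than_disconnected(self):
        g = self._pair_graph()
        linked, unlinked = [], []
        for seed in range(50):
            pos = fr_layout(g, seed=seed)
            linked.append(np.linalg.norm(pos["a"] - pos["b"]))
            unlinked.append(np.linalg.norm(pos["c"] - pos["d"]))
        assert np.mean(linked) < np.mean(unlinked)

    def test_single_node_at_origin(self):
        import networkx as nx

        g = nx.Graph()
        g.add_node("only")
        pos = fr_layout(g, seed=0)
        np.testing.assert_array_equal(pos["only"], np.zeros(2))

    def test_coordinates_finite(self, default_run):
        g = build_network(default_run["subset"], default_run["metadata"])
        pos = fr_layout(g, seed=7)
        assert all(np.isfinite(p).all() for p in pos.values())
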