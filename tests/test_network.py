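import networkx as nx
import numpy as np
import pytest

from reefbiome.network import (CooccurrenceNetwork, build_network,
                               compute_topology, filter_network_otus,
                               identify_keystones, jaccard_index, keystoneness,
                               min_max_scale, network_summary)
from reefbiome.tables import OtuTable


def net_from_graph(g):
    return CooccurrenceNetwork(graph=g, r_threshold=0.8, p_threshold=0.001)


def graph_of(*edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for u, v in edges:
        g.add_edge(u, v, rho=0.9, p=1e-5, sign="pos")
    return g


# ---------------------------------------------------------------------------
# brute-force centrality oracle (BFS shortest-path enumeration)

def brute_force_centralities(g):
    nodes = sorted(g.nodes())
    n = len(nodes)
    btw = {v: 0.0 for v in nodes}
    clo = {}
    for s in nodes:
        # BFS shortest path counts and distances
        dist = {s: 0}
        sigma = {v: 0 for v in nodes}
        sigma[s] = 1
        preds = {v: [] for v in nodes}
        queue = [s]
        order = []
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in g.neighbors(v):
                if w not in dist:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        # accumulate pair dependencies
        delta = {v: 0.0 for v in nodes}
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1 + delta[w])
            if w != s:
                btw[w] += delta[w]
        # closeness with Wasserman-Faust component rescaling
        reach = len(dist) - 1
        total = sum(dist.values())
        if reach > 0 and n > 1:
            clo[s] = (reach / total) * (reach / (n - 1))
        else:
            clo[s] = 0.0
    scale = (n - 1) * (n - 2) if n > 2 else 1
    return {v: btw[v] / scale for v in nodes}, clo


class TestFilter:
    def test_prevalence_is_strict(self):
        counts = np.zeros((6, 3), dtype=int)
        counts[:, 0] = 2           # always present
        counts[:3, 1] = 5          # 3/6 = 0.5, excluded under strict >
        counts[:4, 2] = 5          # 4/6 > 0.5, kept
        t = OtuTable([f"s{i}" for i in range(6)],
                     ["filler", "half", "most"], counts)
        sub = filter_network_otus(t, 0.5, 0.0)
        assert sub.otu_ids == ["filler", "most"]

    def test_zero_thresholds_keep_nonzero_otus(self):
        counts = np.array([[1, 0], [2, 0]])
        t = OtuTable(["a", "b"], ["live", "dead"], counts)
        assert filter_network_otus(t, 0.0, 0.0).otu_ids == ["live"]

    def test_hand_trace_five_otus(self):
        counts = np.array([
            [90, 10, 0, 3, 1],
            [90, 0, 0, 3, 1],
            [90, 10, 1, 3, 0],
            [90, 0, 0, 3, 1],
        ])
        t = OtuTable([f"s{i}" for i in range(4)],
                     ["big", "patchy", "rare", "steady", "thin"], counts)
        # prevalences: 1, .5, .25, 1, .75 ; mean shares: big .87, steady .029
        sub = filter_network_otus(t, 0.5, 0.005)
        assert sub.otu_ids == ["big", "steady", "thin"]
        sub2 = filter_network_otus(t, 0.5, 0.01)
        assert sub2.otu_ids == ["big", "steady"]


class TestBuildNetwork:
    def test_perfect_rank_correlation_positive_edge(self):
        n = 20
        a = np.arange(1, n + 1)
        counts = np.column_stack([a, 2 * a, np.full(n, 500)])
        t = OtuTable([f"s{i}" for i in range(n)], ["a", "b", "c"], counts)
        net = build_network(t)
        assert frozenset(("a", "b")) in net.edge_set()
        e = net.graph.edges["a", "b"]
        assert e["rho"] == pytest.approx(1.0) and e["sign"] == "pos"
        assert net.graph.nodes["a"]["mean_rel_abund"] > 0

    def test_independent_noise_rarely_connects(self):
        empties = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            counts = rng.integers(1, 100, size=(20, 10))
            t = OtuTable([f"s{i}" for i in range(20)],
                         [f"o{j}" for j in range(10)], counts)
            empties += build_network(t).n_edges == 0
        assert empties >= 19

    def test_constant_otu_warns_and_skips(self):
        counts = np.column_stack([np.arange(1, 11), np.arange(1, 11) * 2])
        counts = np.column_stack([counts, np.full(10, 7)])
        # make the constant OTU constant in relative abundance too
        counts = np.column_stack([counts, 1000 - counts.sum(axis=1)])
        t = OtuTable([f"s{i}" for i in range(10)],
                     ["a", "b", "flat", "rest"], counts)
        x = t.relative_abundance()
        if np.ptp(x[:, 2]) == 0:
            with pytest.warns(UserWarning, match="constant"):
                net = build_network(t)
            assert "flat" not in net.nodes

    def test_threshold_monotonicity(self, small_dataset):
        table, design, _, _ = small_dataset
        sub = filter_network_otus(table, 0.5, 0.0001)
        strict = build_network(sub, 0.8, 0.001)
        loose = build_network(sub, 0.7, 0.01)
        assert strict.edge_set() <= loose.edge_set()

    def test_too_few_samples_rejected(self):
        t = OtuTable(["a", "b"], ["o1", "o2"], np.array([[1, 2], [3, 4]]))
        with pytest.raises(ValueError, match="samples"):
            build_network(t)


class TestTopology:
    def test_path_graph_hand_values(self):
        topo = compute_topology(net_from_graph(graph_of(("A", "B"), ("B", "C"))))
        by = {t.otu_id: t for t in topo}
        assert [by[n].degree for n in "ABC"] == [1, 2, 1]
        assert [by[n].betweenness for n in "ABC"] == [0.0, 1.0, 0.0]
        assert by["B"].closeness == pytest.approx(1.0)
        assert by["A"].closeness == pytest.approx(2 / 3)

    def test_star_hand_values(self):
        edges = [("hub", leaf) for leaf in "abcd"]
        topo = compute_topology(net_from_graph(graph_of(*edges)))
        by = {t.otu_id: t for t in topo}
        assert by["hub"].betweenness == pytest.approx(1.0)
        assert by["hub"].closeness == pytest.approx(1.0)
        assert by["a"].betweenness == 0.0

    def test_complete_graph(self):
        g = nx.complete_graph(5)
        topo = compute_topology(net_from_graph(g))
        assert all(t.betweenness == 0 for t in topo)
        assert all(t.closeness == pytest.approx(1.0) for t in topo)

    def test_isolated_node_zeroes(self):
        g = graph_of(("A", "B"), nodes=["lonely"])
        by = {t.otu_id: t for t in compute_topology(net_from_graph(g))}
        assert by["lonely"].closeness == 0.0
        assert by["lonely"].betweenness == 0.0

    def test_matches_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(21)
        for _ in range(30):
            n = rng.integers(3, 25)
            p = rng.uniform(0.05, 0.5)
            g = nx.gnp_random_graph(int(n), float(p),
                                    seed=int(rng.integers(1e6)))
            topo = compute_topology(net_from_graph(g))
            btw_ref, clo_ref = brute_force_centralities(g)
            for t in topo:
                assert t.betweenness == pytest.approx(btw_ref[t.otu_id],
                                                      abs=1e-12)
                assert t.closeness == pytest.approx(clo_ref[t.otu_id],
                                                    abs=1e-12)


class TestKeystoneness:
    def test_min_max_scale(self):
        assert np.allclose(min_max_scale([2, 4, 6]), [0, 0.5, 1])
        assert np.allclose(min_max_scale([3, 3]), [0.5, 0.5])
        v = np.array([1.0, 2.0, 5.0])
        assert np.allclose(min_max_scale(v), min_max_scale(3 * v - 7))

    def test_star_closed_form(self):
        edges = [("hub", leaf) for leaf in "abcd"]
        topo = keystoneness(compute_topology(net_from_graph(graph_of(*edges))))
        by = {t.otu_id: t.keystoneness for t in topo}
        assert by["hub"] == pytest.approx(2 / 3)
        for leaf in "abcd":
            assert by[leaf] == pytest.approx(1 / 3)

    def test_path_closed_form(self):
        topo = keystoneness(
            compute_topology(net_from_graph(graph_of(("A", "B"), ("B", "C")))))
        by = {t.otu_id: t.keystoneness for t in topo}
        assert by["B"] == pytest.approx(2 / 3)
        assert by["A"] == pytest.approx(1 / 3)
        assert by["C"] == pytest.approx(1 / 3)

    def test_complete_graph_all_half(self):
        topo = keystoneness(compute_topology(net_from_graph(nx.complete_graph(4))))
        assert all(t.keystoneness == pytest.approx(0.5) for t in topo)

    def test_keystoneness_bounded(self, small_dataset):
        table, *_ = small_dataset
        sub = filter_network_otus(table, 0.5, 0.0001)
        net = build_network(sub)
        topo = keystoneness(compute_topology(net))
        ks = np.array([t.keystoneness for t in topo])
        assert len(ks) == 0 or ((ks >= 0) & (ks <= 1)).all()


class TestIdentifyKeystones:
    def build_toy(self, abunds):
        g = graph_of(("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"), ("A", "C"))
        for node, ab in abunds.items():
            g.nodes[node]["mean_rel_abund"] = ab
            g.nodes[node]["phylum"] = "Proteobacteria"
        net = net_from_graph(g)
        topo = keystoneness(compute_topology(net))
        return net, topo

    def test_abundance_floor_excludes_top_scorer(self):
        net, topo = self.build_toy(
            {"A": 0.01, "B": 0.01, "C": 0.0005, "D": 0.01, "E": 0.01})
        best = max(topo, key=lambda t: t.keystoneness)
        assert best.otu_id == "C"  # would win without the floor
        recs = identify_keystones(net, topo, top_n=3, min_abund=0.001)
        assert "C" not in [r.otu_id for r in recs]
        assert len(recs) == 3

    def test_fewer_survivors_than_top_n_warns(self):
        net, topo = self.build_toy(
            {"A": 0.01, "B": 0.01, "C": 0.01, "D": 0.0001, "E": 0.0001})
        with pytest.warns(UserWarning, match="pass the keystone"):
            recs = identify_keystones(net, topo, top_n=10, min_abund=0.001)
        assert len(recs) == 3

    def test_tie_broken_by_degree(self):
        g = nx.Graph()
        # two separate cliques of different size: all keystoneness 0.5 within
        for clique, size in (("pqr", 3), ("xy", 2)):
            for i, a in enumerate(clique):
                for b in clique[i + 1:]:
                    g.add_edge(a, b, rho=0.9, p=1e-9, sign="pos")
        for node in g.nodes:
            g.nodes[node]["mean_rel_abund"] = 0.01
        net = net_from_graph(g)
        topo = keystoneness(compute_topology(net))
        recs = identify_keystones(net, topo, top_n=5, min_abund=0.001)
        same_k = [r for r in recs if r.keystoneness ==
                  pytest.approx(recs[0].keystoneness)]
        if len(same_k) > 1:
            degs = [net.graph.degree(r.otu_id) for r in same_k]
            assert degs == sorted(degs, reverse=True)

    def test_abundance_rank_reported(self):
        net, topo = self.build_toy(
            {"A": 0.05, "B": 0.04, "C": 0.03, "D": 0.02, "E": 0.01})
        recs = identify_keystones(net, topo, top_n=5, min_abund=0.001)
        by = {r.otu_id: r for r in recs}
        assert by["A"].abundance_rank == 1
        assert by["E"].abundance_rank == 5


class TestJaccardAndSummary:
    def test_jaccard_cases(self):
        assert jaccard_index({"a", "b"}, {"a", "b"}) == 1.0
        assert jaccard_index({"a"}, {"b"}) == 0.0
        assert jaccard_index({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        with pytest.warns(UserWarning):
            assert jaccard_index(set(), set()) == 0.0

    def test_two_edge_summary(self):
        g = graph_of(("A", "B"), ("B", "C"))
        for n in g.nodes:
            g.nodes[n]["phylum"] = "Chloroflexi"
            g.nodes[n]["mean_rel_abund"] = 0.01
        s = network_summary(net_from_graph(g))
        assert (s["n_nodes"], s["n_edges"]) == (3, 2)
        assert s["n_negative_edges"] == 0
        assert s["phylum_node_counts"] == {"Chloroflexi": 3}

    def test_negative_edges_counted(self):
        g = nx.Graph()
        g.add_edge("A", "B", rho=-0.9, p=1e-9, sign="neg")
        s = network_summary(net_from_graph(g))
        assert s["n_negative_edges"] == 1 and s["n_positive_edges"] == 0


class TestExportRoundTrip:
    def test_edge_tsv_round_trip(self, tmp_path):
        from reefbiome.tables import export_network, read_edge_tsv
        g = graph_of(("A", "B"), ("B", "C"))
        g.edges["A", "B"]["rho"] = -0.85
        g.edges["A", "B"]["sign"] = "neg"
        net = net_from_graph(g)
        p = tmp_path / "net.tsv"
        export_network(net, p, "edge-tsv")
        back = read_edge_tsv(p)
        assert set(map(frozenset, back.edges())) == net.edge_set()
        assert back.edges["A", "B"]["rho"] == pytest.approx(-0.85)
        assert back.edges["A", "B"]["sign"] == "neg"
        assert (tmp_path / "net.tsv.nodes.tsv").exists()

    def test_sif_and_graphml(self, tmp_path):
        from reefbiome.tables import export_network
        g = graph_of(("A", "B"), ("B", "C"))
        for n in g.nodes:
            g.nodes[n]["phylum"] = "Firmicutes"
            g.nodes[n]["mean_rel_abund"] = 0.02
        net = net_from_graph(g)
        export_network(net, tmp_path / "n.sif", "sif")
        lines = (tmp_path / "n.sif").read_text().splitlines()
        assert "A pp B" in lines
        export_network(net, tmp_path / "n.graphml", "graphml")
        back = nx.read_graphml(tmp_path / "n.graphml")
        assert set(back.nodes) == {"A", "B", "C"}
        assert back.nodes["A"]["phylum"] == "Firmicutes"

    def test_empty_network_files(self, tmp_path):
        from reefbiome.tables import export_network
        net = net_from_graph(nx.Graph())
        export_network(net, tmp_path / "e.tsv", "edge-tsv")
        assert (tmp_path / "e.tsv").read_text().startswith("source\t")
        export_network(net, tmp_path / "e.graphml", "graphml")
        assert nx.read_graphml(tmp_path / "e.graphml").number_of_nodes() == 0

    def test_unknown_format_rejected(self, tmp_path):
        from reefbiome.tables import export_network
        with pytest.raises(ValueError, match="format"):
            export_network(net_from_graph(nx.Graph()), tmp_path / "x", "dot")
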