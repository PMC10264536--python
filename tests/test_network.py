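import itertools
import string

import numpy as np
import pandas as pd
import pytest

from seronet.connectivity import ConnectivityMatrix
from seronet.network import (
    ConnectivityNetwork,
    EdgeAttrs,
    build_network,
    compare_networks,
    edge_list_frames,
    export_edge_lists,
    load_edge_list,
    node_degrees,
    percentile_threshold,
)


def matrix_from_rho(rho, ids, p_adjusted=None, label="toxicity0"):
    rho = np.asarray(rho, dtype=float)
    n = np.full_like(rho, 30.0)
    if p_adjusted is None:
        p_adjusted = np.where(np.abs(rho) > 0.5, 0.01, 0.5)
    p_adjusted = np.asarray(p_adjusted, dtype=float)
    np.fill_diagonal(p_adjusted, 0.0)
    p_raw = p_adjusted / 2.0
    df = lambda a: pd.DataFrame(a, index=ids, columns=ids)
    return ConnectivityMatrix(
        group_label=label, rho=df(rho), p_raw=df(p_raw),
        p_adjusted=df(p_adjusted), n_used=df(n),
    )


def make_net(pairs, nodes, label="toxicity0", threshold=0.6, rho=0.9, q=0.01):
    edges = {}
    for pair in pairs:
        r = rho[pair] if isinstance(rho, dict) else rho
        edges[frozenset(pair)] = EdgeAttrs(r, q)
    return ConnectivityNetwork(
        group_label=label,
        nodes=list(nodes),
        functional_groups={n: "" for n in nodes},
        edges=edges,
        threshold_used=threshold,
    )


class TestPercentileThreshold:
    def test_constant_distribution(self):
        rho = np.full((4, 4), 0.6)
        np.fill_diagonal(rho, 1.0)
        mat = matrix_from_rho(rho, list("abcd"))
        for pct in (10, 50, 85, 99):
            assert percentile_threshold([mat], pct) == pytest.approx(0.6)

    def test_hand_linear_interpolation(self):
        # pooled |rho| = 0.1..1.0; h = 9 * 0.85 = 7.65 between the 8th and
        # 9th order statistics: 0.8 + 0.65 * 0.1 = 0.865
        vals = np.arange(0.1, 1.05, 0.1)
        rho = np.eye(5)
        iu = np.triu_indices(5, k=1)
        rho[iu] = vals
        rho.T[iu] = vals
        mat = matrix_from_rho(rho, list("abcde"))
        assert percentile_threshold([mat], 85) == pytest.approx(0.865)

    def test_boundary_is_maximum(self):
        rng = np.random.default_rng(0)
        rho = np.eye(6)
        iu = np.triu_indices(6, k=1)
        vals = rng.uniform(-1, 1, iu[0].size)
        rho[iu] = vals
        rho.T[iu] = vals
        mat = matrix_from_rho(rho, list("abcdef"))
        assert percentile_threshold([mat], 99.999) == pytest.approx(
            np.abs(vals).max(), abs=1e-4
        )

    def test_pools_both_matrices(self):
        rho_a = np.eye(2); rho_a[0, 1] = rho_a[1, 0] = 0.2
        rho_b = np.eye(2); rho_b[0, 1] = rho_b[1, 0] = 0.8
        mats = [matrix_from_rho(rho_a, list("xy")), matrix_from_rho(rho_b, list("xy"), label="toxicity1")]
        assert percentile_threshold(mats, 50) == pytest.approx(0.5)

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            percentile_threshold([], 85)
        rho = np.eye(2)
        with pytest.raises(ValueError):
            percentile_threshold([matrix_from_rho(rho, list("xy"))], 0)


class TestBuildNetwork:
    def make_matrix(self):
        ids = list("abcd")
        rho = np.eye(4)
        entries = {(0, 1): 0.9, (0, 2): 0.7, (1, 2): 0.61, (2, 3): -0.8, (1, 3): 0.6}
        q = {(0, 1): 0.01, (0, 2): 0.2, (1, 2): 0.04, (2, 3): 0.001, (1, 3): 0.001}
        p_adj = np.full((4, 4), 0.5)
        for (i, j), val in entries.items():
            rho[i, j] = rho[j, i] = val
        for (i, j), val in q.items():
            p_adj[i, j] = p_adj[j, i] = val
        return matrix_from_rho(rho, ids, p_adjusted=p_adj)

    def test_joint_rule(self):
        net = build_network(self.make_matrix(), threshold=0.6)
        pairs = net.edge_pairs
        assert frozenset("ab") in pairs          # strong and significant
        assert frozenset("ac") not in pairs      # significance fails
        assert frozenset("cd") in pairs          # negative rho counts by magnitude
        assert net.edges[frozenset("cd")].sign == -1
        assert frozenset("bd") not in pairs      # |rho| == threshold: strict

    def test_isolated_nodes_retained(self):
        net = build_network(self.make_matrix(), threshold=0.89)
        assert set(net.nodes) == set("abcd")
        assert net.edge_pairs == {frozenset("ab")}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(8)
        ids = list(string.ascii_lowercase[:10])
        rho = np.eye(10)
        iu = np.triu_indices(10, k=1)
        vals = rng.uniform(-1, 1, iu[0].size)
        rho[iu] = vals
        rho.T[iu] = vals
        mat = matrix_from_rho(rho, ids)
        previous = None
        for thr in (0.1, 0.3, 0.5, 0.7, 0.9):
            edges = build_network(mat, thr).edge_pairs
            if previous is not None:
                assert edges <= previous
            previous = edges


class TestNodeDegrees:
    def test_empty_network(self):
        net = make_net([], list("abc"))
        assert node_degrees(net) == {"a": 0, "b": 0, "c": 0}

    def test_triangle(self):
        net = make_net([("a", "b"), ("a", "c"), ("b", "c")], list("abc"))
        degrees = node_degrees(net)
        assert degrees == {"a": 2, "b": 2, "c": 2}
        assert sum(degrees.values()) == 2 * net.n_edges

    def test_handshake_on_random_networks(self):
        rng = np.random.default_rng(12)
        nodes = list(string.ascii_lowercase[:20])
        all_pairs = list(itertools.combinations(nodes, 2))
        for _ in range(20):
            chosen = [all_pairs[i] for i in rng.choice(len(all_pairs), 30, replace=False)]
            net = make_net(chosen, nodes)
            degrees = node_degrees(net)
            assert sum(degrees.values()) == 2 * len(chosen)
            # brute-force incidence count
            for node in nodes:
                assert degrees[node] == sum(node in p for p in chosen)


class TestCompareNetworks:
    def test_identity_comparison(self):
        pairs = [("a", "b"), ("b", "c")]
        net = make_net(pairs, list("abc"))
        comp = compare_networks(net, net)
        assert comp.shared_edges == net.edge_pairs
        assert not comp.specific_to_group0 and not comp.specific_to_group1
        assert comp.degree0 == comp.degree1

    def test_disjoint_edge_sets(self):
        nodes = list("abcdefgh")
        net0 = make_net([("a", "b"), ("c", "d"), ("e", "f")], nodes)
        net1 = make_net([("a", "c"), ("b", "d"), ("e", "g"), ("f", "h")], nodes,
                        label="toxicity1")
        comp = compare_networks(net0, net1)
        assert not comp.shared_edges
        assert len(comp.specific_to_group0) == 3
        assert len(comp.specific_to_group1) == 4

    def test_matches_brute_force_on_random_networks(self):
        rng = np.random.default_rng(9)
        nodes = list(string.ascii_lowercase[:10])
        all_pairs = list(itertools.combinations(nodes, 2))
        for _ in range(25):
            e0 = {frozenset(all_pairs[i]) for i in rng.choice(len(all_pairs), 12, replace=False)}
            e1 = {frozenset(all_pairs[i]) for i in rng.choice(len(all_pairs), 15, replace=False)}
            comp = compare_networks(
                make_net(e0, nodes), make_net(e1, nodes, label="toxicity1")
            )
            shared = {p for p in e0 if p in e1}
            assert comp.shared_edges == shared
            assert comp.specific_to_group0 == {p for p in e0 if p not in e1}
            assert comp.specific_to_group1 == {p for p in e1 if p not in e0}

    def test_sign_sensitive_matching(self):
        nodes = list("ab")
        pos = make_net([("a", "b")], nodes, rho=0.9)
        neg = make_net([("a", "b")], nodes, rho=-0.9, label="toxicity1")
        assert compare_networks(pos, neg).shared_edges == {frozenset("ab")}
        comp = compare_networks(pos, neg, sign_sensitive=True)
        assert not comp.shared_edges

    def test_node_mismatch_rejected(self):
        with pytest.raises(ValueError, match="node set"):
            compare_networks(make_net([], list("abc")), make_net([], list("abd")))


class TestEdgeListExport:
    def build_comparison(self):
        nodes = list("abcde")
        net0 = make_net([("a", "b"), ("b", "c"), ("d", "e")], nodes)
        net1 = make_net([("b", "c"), ("c", "d")], nodes, label="toxicity1")
        return compare_networks(net0, net1)

    def test_round_trip(self, tmp_path):
        comp = self.build_comparison()
        paths = export_edge_lists(comp, tmp_path)
        assert load_edge_list(paths["network_toxicity0"]) == comp.net0.edge_pairs
        assert load_edge_list(paths["shared"]) == comp.shared_edges
        assert load_edge_list(paths["specific_toxicity1"]) == comp.specific_to_group1

    def test_decomposition_row_counts(self, tmp_path):
        comp = self.build_comparison()
        paths = export_edge_lists(comp, tmp_path)
        count = lambda name: len(pd.read_csv(paths[name], sep="\t"))
        assert count("shared") + count("specific_toxicity0") == count("network_toxicity0")
        assert count("shared") + count("specific_toxicity1") == count("network_toxicity1")

    def test_canonical_alphabetical_order(self):
        frames = edge_list_frames(self.build_comparison())
        for frame in frames.values():
            assert (frame["analyte_a"] < frame["analyte_b"]).all()
            pairs = list(zip(frame["analyte_a"], frame["analyte_b"]))
            assert pairs == sorted(pairs)

    def test_empty_comparison_writes_headers(self, tmp_path):
        nodes = list("abc")
        comp = compare_networks(
            make_net([], nodes), make_net([], nodes, label="toxicity1")
        )
        paths = export_edge_lists(comp, tmp_path)
        for path in paths.values():
            frame = pd.read_csv(path, sep="\t")
            assert list(frame.columns) == ["analyte_a", "analyte_b", "rho", "p_adjusted"]
            assert frame.empty
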