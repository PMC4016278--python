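"""Interactome filtering, subnetwork construction, hub ranking, exports."""

import hashlib

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from netmark.errors import FormatError
from netmark.network import (
    build_network,
    edge_coexpression,
    filter_edges,
    hub_ranking,
    read_edge_list,
    read_sif,
    restrict_to_expression,
    write_network,
)

from conftest import make_em


def edges_df(pairs, r=None):
    df = pd.DataFrame(
        [(a, b) if a <= b else (b, a) for a, b in pairs], columns=["gene_a", "gene_b"]
    )
    if r is not None:
        df["r_edge"] = r
    return df


class TestReadEdgeList:
    def test_unordered_dedup_and_self_loop_drop(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\nB\tA\nC\tC\nB\tD\n")
        edges = read_edge_list(p)
        assert set(map(tuple, edges.to_numpy())) == {("A", "B"), ("B", "D")}

    def test_malformed_line_reports_line_number(self, tmp_path):
        p = tmp_path / "edges.tsv"
        p.write_text("A\tB\njustone\n")
        with pytest.raises(FormatError, match=":2"):
            read_edge_list(p)


class TestRestrictAndCoexpression:
    def test_all_present_is_identity(self):
        em = make_em(np.eye(3), gene_ids=list("ABC"))
        e = edges_df([("A", "B"), ("B", "C")])
        assert restrict_to_expression(e, em).equals(e)

    def test_absent_endpoint_dropped_matches_membership_oracle(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(30)]
        em = make_em(rng.normal(size=(20, 5)), gene_ids=genes[:20])
        pairs = [
            (genes[i], genes[j])
            for i, j in rng.integers(0, 30, size=(50, 2))
            if i != j
        ]
        e = edges_df(pairs).drop_duplicates().reset_index(drop=True)
        kept = restrict_to_expression(e, em)
        present = set(genes[:20])
        expected = {
            (a, b) for a, b in map(tuple, e.to_numpy()) if a in present and b in present
        }
        assert set(map(tuple, kept.to_numpy())) == expected

    def test_identical_and_negated_profiles(self):
        x = np.array([1.0, 2.0, 5.0, 3.0])
        em = make_em([x, x, 2 * x.mean() - x], gene_ids=["A", "B", "C"])
        out = edge_coexpression(edges_df([("A", "B"), ("A", "C")]), em)
        r = dict(zip(map(tuple, out[["gene_a", "gene_b"]].to_numpy()), out["r_edge"]))
        assert r[("A", "B")] == pytest.approx(1.0)
        assert r[("A", "C")] == pytest.approx(-1.0)

    def test_matches_textbook_pearson_oracle(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(10, 20))
        em = make_em(x)
        pairs = [(f"g{i}", f"g{j}") for i in range(10) for j in range(i + 1, 10)]
        out = edge_coexpression(edges_df(pairs), em)
        for (a, b), r in zip(map(tuple, out[["gene_a", "gene_b"]].to_numpy()), out["r_edge"]):
            i, j = int(a[1:]), int(b[1:])
            xi, xj = x[i] - x[i].mean(), x[j] - x[j].mean()
            ref = (xi * xj).sum() / np.sqrt((xi**2).sum() * (xj**2).sum())
            assert r == pytest.approx(ref, abs=1e-12)

    def test_zero_variance_endpoint_flagged_as_zero(self):
        em = make_em([[1, 2, 3], [4, 4, 4]], gene_ids=["A", "B"])
        out = edge_coexpression(edges_df([("A", "B")]), em)
        assert out["r_edge"].iloc[0] == 0.0


class TestFilterEdges:
    def test_strict_boundary_and_sign(self):
        e = edges_df([("A", "B"), ("C", "D"), ("E", "F"), ("G", "H")],
                     r=[0.8, -0.81, 0.9, -0.8])
        kept = filter_edges(e, 0.8)
        assert set(map(tuple, kept[["gene_a", "gene_b"]].to_numpy())) == {
            ("C", "D"), ("E", "F"),
        }

    def test_matches_filter_oracle_and_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        e = edges_df(
            [(f"a{i}", f"b{i}") for i in range(100)], r=rng.uniform(-1, 1, 100)
        )
        for t in (0.2, 0.5, 0.8):
            kept = filter_edges(e, t)
            assert len(kept) == int((e["r_edge"].abs() > t).sum())
        sizes = [len(filter_edges(e, t)) for t in (0.1, 0.4, 0.7, 0.95)]
        assert sizes == sorted(sizes, reverse=True)


class TestBuildNetwork:
    def test_full_membership_keeps_all_edges(self):
        e = edges_df([("A", "B"), ("B", "C")], r=[0.9, 0.95])
        net = build_network(e, {"A", "B", "C"})
        assert net.n_edges == 2 and net.nodes == {"A", "B", "C"}

    def test_empty_membership_gives_empty_network(self):
        e = edges_df([("A", "B")], r=[0.9])
        net = build_network(e, set())
        assert net.n_edges == 0 and net.nodes == set()

    def test_both_vs_any_endpoint_rule(self):
        e = edges_df([("A", "B"), ("B", "C")], r=[0.9, 0.9])
        assert build_network(e, {"A", "B"}, "both").n_edges == 1
        assert build_network(e, {"A", "B"}, "any").n_edges == 2

    def test_handshake_lemma_and_union_of_endpoints(self):
        rng = np.random.default_rng(3)
        pairs = {
            tuple(sorted((f"g{i}", f"g{j}")))
            for i, j in rng.integers(0, 15, size=(40, 2))
            if i != j
        }
        e = edges_df(sorted(pairs), r=rng.uniform(-1, 1, len(pairs)))
        members = {f"g{i}" for i in range(0, 15, 2)}
        net = build_network(e, members)
        assert sum(net.degree.values()) == 2 * net.n_edges
        expected_nodes = set()
        for a, b in map(tuple, e[["gene_a", "gene_b"]].to_numpy()):
            if a in members and b in members:
                expected_nodes |= {a, b}
        assert net.nodes == expected_nodes
        assert all(d >= 1 for d in net.degree.values())


class TestHubRanking:
    def test_star_center_ranks_first(self):
        e = edges_df([("Z", f"n{i}") for i in range(5)], r=[0.9] * 5)
        net = build_network(e, {"Z"} | {f"n{i}" for i in range(5)})
        ranked = hub_ranking(net)
        assert ranked[0] == ("Z", 5)

    def test_triangle_ties_break_lexicographically(self):
        e = edges_df([("A", "B"), ("B", "C"), ("A", "C")], r=[0.9] * 3)
        net = build_network(e, {"A", "B", "C"})
        assert hub_ranking(net) == [("A", 2), ("B", 2), ("C", 2)]
        assert hub_ranking(net, top_k=2) == [("A", 2), ("B", 2)]

    def test_triangle_fixture_every_degree_two(self):
        e = edges_df([("A", "B"), ("B", "C"), ("A", "C")], r=[0.9] * 3)
        net = build_network(e, {"A", "B", "C"})
        assert set(net.degree.values()) == {2}


class TestWriteNetwork:
    @pytest.fixture()
    def net(self):
        e = edges_df([("A", "B"), ("B", "C")], r=[0.91, -0.85])
        return build_network(e, {"A", "B", "C"})

    def test_sif_roundtrip_and_single_edge_format(self, tmp_path, net):
        p = tmp_path / "net.sif"
        write_network(net, p, "sif")
        back = read_sif(p)
        assert back.nodes == net.nodes and back.n_edges == net.n_edges
        one = build_network(edges_df([("A", "B")], r=[0.9]), {"A", "B"})
        p1 = tmp_path / "one.sif"
        write_network(one, p1, "sif")
        assert p1.read_text() == "A\tpp\tB\n"

    def test_graphml_roundtrip_preserves_attributes(self, tmp_path, net):
        p = tmp_path / "net.graphml"
        write_network(net, p, "graphml")
        g = nx.read_graphml(p)
        assert set(g.nodes) == net.nodes
        assert g.nodes["B"]["degree"] == 2
        assert g.edges[("A", "B")]["r_edge"] == pytest.approx(0.91)

    def test_checksum_determinism(self, tmp_path, net):
        digests = []
        for name in ("x.sif", "y.sif"):
            p = tmp_path / name
            write_network(net, p, "sif")
            digests.append(hashlib.sha256(p.read_bytes()).hexdigest())
        assert digests[0] == digests[1]


def test_pipeline_monotonicity_raising_thresholds_never_adds(default_bundle):
    """Raising either |r| threshold can only shrink the final network."""
    import numpy as np
    from netmark.preprocess import log2_transform, normalize_global
    from netmark.pheno import phenotype_correlation, select_phenotype_genes

    em = log2_transform(normalize_global(default_bundle.expression))
    coexpr = edge_coexpression(default_bundle.edges, em)
    r = phenotype_correlation(em, default_bundle.labels)
    prev_nodes, prev_edges = None, None
    for t in (0.5, 0.7, 0.8, 0.9):
        members = select_phenotype_genes(r, t)
        net = build_network(filter_edges(coexpr, t), members)
        if prev_nodes is not None:
            assert net.nodes <= prev_nodes
            assert set(map(tuple, net.edge_table()[["gene_a", "gene_b"]].to_numpy())) <= prev_edges
        prev_nodes = net.nodes
        prev_edges = set(map(tuple, net.edge_table()[["gene_a", "gene_b"]].to_numpy()))
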