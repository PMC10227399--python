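"""Graph materialization, strain edges, summaries, exports, invariants."""

import json

import pytest

from cannanet.association import decide_edges
from cannanet.cooccurrence import CooccurrenceCounts, counts_from_matrix, pair_key
from cannanet.graph import (
    add_strain_edges,
    average_degree,
    build_graph,
    graph_summary,
    node_id,
    read_json_graph,
    validate_graph,
    write_edgelist,
    write_graphml,
    write_json_graph,
)
from cannanet.synthetic import generate_presence
from tests.conftest import planted_spec


def _single_pair_counts():
    counts = CooccurrenceCounts(
        N=10,
        occ={("cbd", "chemical"): 2, ("analgesic", "property"): 2},
        pair_occ={pair_key(("cbd", "chemical"), ("analgesic", "property")): 1},
        pair_weight={pair_key(("cbd", "chemical"), ("analgesic", "property")): 6},
        pair_paragraphs={
            pair_key(("cbd", "chemical"), ("analgesic", "property")): {("d", 3)}
        },
    )
    return counts


class TestBuildGraph:
    def test_single_edge_construction(self):
        counts = _single_pair_counts()
        g = build_graph(counts, decide_edges(counts))
        assert g.number_of_nodes() == 2
        assert g.number_of_edges() == 1
        (u, v, data), = g.edges(data=True)
        assert data["weight"] == 6
        assert data["provenance"] == [("d", 3)]
        assert data["relation"] == "chemical_property"

    def test_mode_semantics(self):
        counts = _single_pair_counts()
        results = decide_edges(counts, alpha=1e-6)
        assert not results[0].significant  # a single weak pair
        permissive = build_graph(counts, results, mode="permissive")
        strict = build_graph(counts, results, mode="significant_only")
        assert permissive.number_of_edges() == 1
        assert strict.number_of_edges() == 0

    def test_include_isolated_entities(self):
        counts = _single_pair_counts()
        counts.occ[("thcas", "gene")] = 1
        g = build_graph(counts, decide_edges(counts), include_isolated_entities=True)
        assert node_id(("thcas", "gene")) in g
        assert g.degree(node_id(("thcas", "gene"))) == 0

    def test_unknown_pair_in_results_rejected(self):
        counts = _single_pair_counts()
        results = decide_edges(counts)
        with pytest.raises(ValueError, match="unseen pair"):
            build_graph(CooccurrenceCounts(N=1), results)

    def test_same_name_different_types_not_merged(self):
        counts = CooccurrenceCounts(
            N=5,
            occ={("cbdas", "gene"): 1, ("cbdas", "chemical"): 1},
            pair_occ={pair_key(("cbdas", "gene"), ("cbdas", "chemical")): 1},
            pair_weight={pair_key(("cbdas", "gene"), ("cbdas", "chemical")): 1},
            pair_paragraphs={pair_key(("cbdas", "gene"), ("cbdas", "chemical")): {("d", 0)}},
        )
        g = build_graph(counts, decide_edges(counts))
        assert g.number_of_nodes() == 2  # no self-edge, two typed nodes
        validate_graph(g)


class TestStrainEdges:
    def test_one_strain_three_chemicals(self):
        g = build_graph(_single_pair_counts(), [])
        add_strain_edges(g, [("blackberry kush", c) for c in ("limonene", "myrcene", "pinene")])
        strains = [n for n, d in g.nodes(data=True) if d["etype"] == "strain"]
        assert len(strains) == 1
        assert g.degree(strains[0]) == 3
        validate_graph(g)

    def test_duplicate_rows_idempotent(self):
        g = build_graph(_single_pair_counts(), [])
        rows = [("kush", "limonene"), ("kush", "limonene")]
        add_strain_edges(g, rows)
        assert g.number_of_edges() == 1

    def test_nine_strain_fixture(self, tmp_path):
        # mirrors the nine-strain constituent table added by hand
        rows = [f"strain{i}\tlimonene" for i in range(9)]
        table = tmp_path / "strains.tsv"
        table.write_text("\n".join(rows) + "\n")
        g = build_graph(_single_pair_counts(), [])
        add_strain_edges(g, table)
        assert sum(1 for _n, d in g.nodes(data=True) if d["etype"] == "strain") == 9

    def test_malformed_row_names_line(self, tmp_path):
        table = tmp_path / "bad.tsv"
        table.write_text("strain1\tlimonene\nonly-one-column\n")
        g = build_graph(_single_pair_counts(), [])
        with pytest.raises(ValueError, match=":2"):
            add_strain_edges(g, table)


class TestGraphSummary:
    def test_published_scale_average_degree(self):
        # the full-corpus network: 29,862 nodes and 389,334 edges round to
        # a mean degree of 26
        assert int(round(average_degree(29_862, 389_334))) == 26

    def test_published_scale_type_counts_sum(self):
        assert 20_495 + 8_978 + 380 + 9 == 29_862

    def test_single_edge_graph(self):
        counts = _single_pair_counts()
        g = build_graph(counts, decide_edges(counts))
        s = graph_summary(g)
        assert s["average_degree"] == 1.0
        assert s["node_count_by_type"] == {"chemical": 1, "property": 1}

    def test_empty_graph(self):
        g = build_graph(CooccurrenceCounts(N=1), [])
        s = graph_summary(g)
        assert s == {
            "node_count": 0,
            "node_count_by_type": {},
            "edge_count": 0,
            "average_degree": 0,
            "average_degree_rounded": 0,
        }


class TestInvariantsOnBuiltGraphs:
    @pytest.fixture(scope="class")
    def built(self):
        truth = generate_presence(planted_spec(seed=33, n_docs=20))
        counts = counts_from_matrix(truth.mention_counts, truth.entities)
        g = build_graph(counts, decide_edges(counts))
        add_strain_edges(g, [("kush", "cbda"), ("haze", "cbga")])
        return g, counts

    def test_handshake_identity(self, built):
        g, _ = built
        assert sum(d for _n, d in g.degree()) == 2 * g.number_of_edges()

    def test_no_inadmissible_edges(self, built):
        g, _ = built
        validate_graph(g)

    def test_weight_and_provenance_conservation(self, built):
        g, counts = built
        for u, v, data in g.edges(data=True):
            if data["relation"] == "strain_chemical":
                assert data["weight"] == 1 and data["provenance"] == []
                continue
            e1 = (g.nodes[u]["canonical"], g.nodes[u]["etype"])
            e2 = (g.nodes[v]["canonical"], g.nodes[v]["etype"])
            key = pair_key(e1, e2)
            assert data["weight"] == counts.pair_weight[key]
            assert len(data["provenance"]) == counts.pair_occ[key]
            assert data["weight"] >= len(data["provenance"])

    def test_rebuild_is_idempotent(self, built, tmp_path):
        g, counts = built
        g2 = build_graph(counts, decide_edges(counts))
        add_strain_edges(g2, [("kush", "cbda"), ("haze", "cbga")])
        write_json_graph(g, tmp_path / "a.json")
        write_json_graph(g2, tmp_path / "b.json")
        assert (tmp_path / "a.json").read_text() == (tmp_path / "b.json").read_text()


class TestExports:
    @pytest.fixture(scope="class")
    def graph(self):
        counts = _single_pair_counts()
        g = build_graph(counts, decide_edges(counts))
        add_strain_edges(g, [("kush", "cbd")])
        return g

    def test_json_roundtrip(self, graph, tmp_path):
        write_json_graph(graph, tmp_path / "g.json")
        back = read_json_graph(tmp_path / "g.json")
        assert set(back.nodes) == set(graph.nodes)
        assert set(map(frozenset, back.edges)) == set(map(frozenset, graph.edges))
        for u, v, data in graph.edges(data=True):
            assert back.edges[u, v]["weight"] == data["weight"]
            assert back.edges[u, v]["provenance"] == data["provenance"]

    def test_graphml_export_readable(self, graph, tmp_path):
        import networkx as nx

        write_graphml(graph, tmp_path / "g.graphml")
        back = nx.read_graphml(tmp_path / "g.graphml")
        assert back.number_of_nodes() == graph.number_of_nodes()
        nid = node_id(("cbd", "chemical"))
        assert back.nodes[nid]["etype"] == "chemical"
        assert back.nodes[nid]["degree"] == graph.degree(nid)

    def test_edgelist_columns(self, graph, tmp_path):
        write_edgelist(graph, tmp_path / "e.tsv")
        lines = (tmp_path / "e.tsv").read_text().splitlines()
        assert lines[0].split("\t")[:4] == ["node_u", "node_v", "relation", "weight"]
        assert len(lines) == 1 + graph.number_of_edges()
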