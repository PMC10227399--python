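"""Neighbor subgraphs, degree filtering, heatmaps, and provenance recall."""

import networkx as nx
import numpy as np
import pytest

from cannanet.association import decide_edges
from cannanet.cooccurrence import counts_from_matrix
from cannanet.graph import build_graph, node_id
from cannanet.query import (
    QueryError,
    Subgraph,
    filter_by_degree,
    heatmap_matrix,
    neighbor_subgraph,
    recall_provenance,
    write_heatmap_csv,
)
from cannanet.synthetic import build_lexicon, generate
from cannanet.lexicon import match_entities
from cannanet.pipeline import run_pipeline_in_memory
from tests.conftest import planted_spec


def _typed_graph(edges):
    """edges: iterable of ((name, etype), (name, etype), weight)."""
    g = nx.Graph()
    for (c1, t1), (c2, t2), w in edges:
        for c, t in ((c1, t1), (c2, t2)):
            g.add_node(node_id((c, t)), canonical=c, etype=t)
        rel = "strain_chemical" if "strain" in (t1, t2) else (
            "gene_chemical" if "gene" in (t1, t2) else "chemical_property"
        )
        g.add_edge(node_id((c1, t1)), node_id((c2, t2)), relation=rel, weight=w, provenance=[])
    return g


@pytest.fixture
def star():
    """Center chemical with five property leaves."""
    return _typed_graph(
        [(("hub", "chemical"), (f"leaf{i}", "property"), 1) for i in range(5)]
    )


class TestNeighborSubgraph:
    def test_one_hop_neighborhood(self, star):
        sub = neighbor_subgraph(star, ["hub"])
        assert len(sub) == 6
        assert sub.graph.number_of_edges() == 5

    def test_shared_neighbors_appear_once(self):
        g = _typed_graph(
            [
                (("cbd", "chemical"), ("antiviral", "property"), 1),
                (("ribavirin", "chemical"), ("antiviral", "property"), 2),
            ]
        )
        sub = neighbor_subgraph(g, ["cbd", "ribavirin"])
        assert len(sub) == 3

    def test_induced_edges_match_brute_force(self):
        truth_spec = planted_spec(seed=44, n_docs=30)
        from cannanet.synthetic import generate_presence

        truth = generate_presence(truth_spec)
        counts = counts_from_matrix(truth.mention_counts, truth.entities)
        g = build_graph(counts, decide_edges(counts))
        sub = neighbor_subgraph(g, ["cbda"])
        expected = {
            frozenset((u, v))
            for u, v in g.edges
            if u in sub.nodes and v in sub.nodes
        }
        assert {frozenset(e) for e in sub.graph.edges} == expected

    def test_ambiguous_name_resolves_all_types(self):
        g = _typed_graph(
            [
                (("cbdas", "gene"), ("cbda", "chemical"), 1),
                (("cbdas", "chemical"), ("analgesic", "property"), 1),
            ]
        )
        sub = neighbor_subgraph(g, ["cbdas"])
        assert node_id(("cbdas", "gene")) in sub.anchors
        assert node_id(("cbdas", "chemical")) in sub.anchors

    def test_unresolvable_name_suggests_near_misses(self, star):
        with pytest.raises(QueryError, match="hub"):
            neighbor_subgraph(star, ["hubb"])
        with pytest.raises(QueryError):
            neighbor_subgraph(star, ["completely unrelated"])

    def test_multi_hop(self):
        g = _typed_graph(
            [
                (("g1", "gene"), ("c1", "chemical"), 1),
                (("c1", "chemical"), ("p1", "property"), 1),
            ]
        )
        assert len(neighbor_subgraph(g, ["g1"], hops=1)) == 2
        assert len(neighbor_subgraph(g, ["g1"], hops=2)) == 3


class TestFilterByDegree:
    def test_min_degree_zero_is_identity(self, star):
        sub = neighbor_subgraph(star, ["hub"])
        out = filter_by_degree(sub, 0, protect_anchors=False)
        assert out.nodes == sub.nodes

    def test_star_filter_shows_degree_shrinkage(self, star):
        # leaves (degree 1) drop at threshold 2; the surviving center's
        # local degree then recomputes to 0
        sub = neighbor_subgraph(star, ["hub"])
        out = filter_by_degree(sub, 2, protect_anchors=False)
        assert out.nodes == {node_id(("hub", "chemical"))}
        assert out.local_degree[node_id(("hub", "chemical"))] == 0

    def test_anchor_protection(self, star):
        sub = neighbor_subgraph(star, ["leaf0"])
        out = filter_by_degree(sub, 3, protect_anchors=True)
        assert node_id(("leaf0", "property")) in out.nodes
        out2 = filter_by_degree(sub, 3, protect_anchors=False)
        assert node_id(("leaf0", "property")) not in out2.nodes

    def test_progressive_filtering_monotone(self):
        rng = np.random.default_rng(0)
        g = nx.Graph()
        for i in range(40):
            g.add_node(f"chemical:c{i}", canonical=f"c{i}", etype="chemical")
            g.add_node(f"property:p{i}", canonical=f"p{i}", etype="property")
        for i in range(40):
            for j in rng.choice(40, size=rng.integers(1, 12), replace=False):
                g.add_edge(
                    f"chemical:c{i}", f"property:p{j}",
                    relation="chemical_property", weight=1, provenance=[],
                )
        sub = Subgraph(anchors=frozenset(), graph=g)
        sizes = [len(sub)]
        for threshold in (4, 5, 9):
            sub = filter_by_degree(sub, threshold, protect_anchors=False)
            sizes.append(len(sub))
        assert sizes == sorted(sizes, reverse=True)
        assert sizes[-1] < sizes[0]

    def test_iterate_reaches_fixed_point(self, star):
        sub = neighbor_subgraph(star, ["hub"])
        out = filter_by_degree(sub, 2, protect_anchors=False, iterate=True)
        again = filter_by_degree(out, 2, protect_anchors=False, iterate=True)
        assert out.nodes == again.nodes == set()


class TestHeatmapMatrix:
    def test_single_edge_matrix(self):
        g = _typed_graph([(("limonene", "chemical"), ("analgesic", "property"), 7)])
        sub = Subgraph(anchors=frozenset(), graph=g)
        M, rows, cols = heatmap_matrix(sub, "chemical", "property")
        assert M.tolist() == [[7.0]]
        assert rows == ["limonene"] and cols == ["analgesic"]

    def test_missing_edge_is_zero_and_total_matches(self):
        edges = [
            (("limonene", "chemical"), ("analgesic", "property"), 7),
            (("myrcene", "chemical"), ("antioxidant", "property"), 3),
        ]
        g = _typed_graph(edges)
        sub = Subgraph(anchors=frozenset(), graph=g)
        M, rows, cols = heatmap_matrix(sub, "chemical", "property")
        assert M.shape == (2, 2)
        assert M.sum() == 10  # equals total chemical-property edge weight
        assert M[rows.index("limonene"), cols.index("antioxidant")] == 0

    def test_row_sums_equal_summed_edge_weights(self):
        # oracle: direct summation over the edge list, monoterpene-style fixture
        rng = np.random.default_rng(1)
        chems = [f"mono{i}" for i in range(6)]
        props = [f"prop{j}" for j in range(4)]
        edges = []
        for c in chems:
            for p in props:
                if rng.random() < 0.6:
                    edges.append(((c, "chemical"), (p, "property"), int(rng.integers(1, 9))))
        g = _typed_graph(edges)
        sub = Subgraph(anchors=frozenset(), graph=g)
        M, rows, cols = heatmap_matrix(sub, "chemical", "property")
        expected = {c: sum(w for (cc, _t), _p, w in edges if cc == c) for c in chems}
        for i, c in enumerate(rows):
            assert M[i].sum() == expected[c]

    def test_absent_type_rejected(self):
        g = _typed_graph([(("c", "chemical"), ("p", "property"), 1)])
        sub = Subgraph(anchors=frozenset(), graph=g)
        with pytest.raises(ValueError, match="gene"):
            heatmap_matrix(sub, "gene", "chemical")

    def test_csv_export(self, tmp_path):
        g = _typed_graph([(("c", "chemical"), ("p", "property"), 2)])
        sub = Subgraph(anchors=frozenset(), graph=g)
        M, rows, cols = heatmap_matrix(sub, "chemical", "property")
        write_heatmap_csv(M, rows, cols, tmp_path / "h.csv")
        assert (tmp_path / "h.csv").read_text().splitlines() == [",p", "c,2"]


class TestRecallProvenance:
    @pytest.fixture(scope="class")
    def built(self):
        spec = planted_spec(seed=55, n_docs=20, paras_per_doc=30)
        docs, _truth = generate(spec)
        lexicon = build_lexicon(spec)
        graph, _results, _summary = run_pipeline_in_memory(docs, lexicon)
        return spec, docs, lexicon, graph

    def test_every_returned_paragraph_contains_both_entities(self, built):
        # oracle: re-run the entity matcher on the returned text
        _spec, docs, lexicon, graph = built
        from cannanet.corpus import Paragraph

        for u, v in list(graph.edges)[:20]:
            ents = {
                (graph.nodes[n]["canonical"], graph.nodes[n]["etype"]) for n in (u, v)
            }
            for text, citation in recall_provenance(graph, (u, v), docs):
                found = {
                    m.entity for m in match_entities(Paragraph("x", 0, text), lexicon)
                }
                assert ents <= found
                assert citation["doc_id"].startswith("syn")

    def test_strain_edge_returns_empty(self, built):
        _spec, docs, _lexicon, graph = built
        from cannanet.graph import add_strain_edges

        add_strain_edges(graph, [("kush", "cbda")])
        edge = (node_id(("kush", "strain")), node_id(("cbda", "chemical")))
        assert recall_provenance(graph, edge, docs) == []

    def test_absent_edge_rejected(self, built):
        _spec, docs, _lexicon, graph = built
        with pytest.raises(KeyError):
            recall_provenance(graph, ("no:such", "edge:here"), docs)

    def test_missing_document_partial_result(self, built, caplog):
        _spec, docs, _lexicon, graph = built
        edge = next(iter(graph.edges))
        full = recall_provenance(graph, edge, docs)
        partial = recall_provenance(graph, edge, docs[1:])
        assert len(partial) <= len(full)
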