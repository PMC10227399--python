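"""Multipartite network materialization, strain edges, summaries and exports.

Nodes are typed (gene / chemical / property / strain) and identified by
``etype:canonical`` — the same string may exist as both a chemical and a gene
node without merging.  The graph is undirected; edges carry the mined weight
(summed per-paragraph mention-count products), the association-test
attributes, and paragraph-level provenance with citation metadata so the
supporting text can be recalled for any edge.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

from .association import AssociationResult
from .cooccurrence import CooccurrenceCounts, Entity

__all__ = [
    "node_id",
    "build_graph",
    "add_strain_edges",
    "graph_summary",
    "average_degree",
    "validate_graph",
    "write_graphml",
    "write_edgelist",
    "write_json_graph",
]

ADMISSIBLE_RELATIONS = {
    frozenset(("gene", "chemical")): "gene_chemical",
    frozenset(("chemical", "property")): "chemical_property",
    frozenset(("strain", "chemical")): "strain_chemical",
}


def node_id(entity: Entity) -> str:
    canonical, etype = entity
    return f"{etype}:{canonical}"


def _ensure_node(g: nx.Graph, entity: Entity) -> str:
    nid = node_id(entity)
    if nid not in g:
        g.add_node(nid, canonical=entity[0], etype=entity[1])
    return nid


def build_graph(
    counts: CooccurrenceCounts,
    assoc: Sequence[AssociationResult],
    mode: str = "permissive",
    include_isolated_entities: bool = False,
    citations: Mapping[str, dict] | None = None,
) -> nx.Graph:
    """Materialize the mined co-occurrence network.

    ``permissive`` mode keeps every scored pair with the significance flag
    as an attribute; ``significant_only`` keeps only pairs passing the test.
    Edge weight and provenance come straight from the accumulated counts.
    With ``include_isolated_entities`` every mentioned entity becomes a node
    even without a retained edge.
    """
    if mode not in ("permissive", "significant_only"):
        raise ValueError(f"unknown build mode {mode!r}")
    known_pairs = set(counts.pair_occ)
    for r in assoc:
        if r.pair not in known_pairs:
            raise ValueError(f"association result for unseen pair {r.pair}")

    g = nx.Graph(mode=mode, n_paragraphs=counts.N)
    for r in assoc:
        if mode == "significant_only" and not r.significant:
            continue
        u = _ensure_node(g, r.entity_a)
        v = _ensure_node(g, r.entity_g)
        provenance = sorted(counts.pair_paragraphs.get(r.pair, ()))
        cited = []
        if citations:
            cited = sorted({doc for doc, _ in provenance if doc in citations})
        g.add_edge(
            u,
            v,
            relation=r.relation,
            weight=r.weight,
            llr=r.llr,
            significant=r.significant,
            direction=r.direction,
            provenance=provenance,
            citations=[citations[d] for d in cited] if citations else [],
        )
    if include_isolated_entities:
        for ent in counts.entities():
            _ensure_node(g, ent)
    return g


def add_strain_edges(
    g: nx.Graph,
    table: str | Path | Iterable[tuple[str, str]],
) -> nx.Graph:
    """Add manually curated strain→chemical edges (weight 1, no test attrs).

    ``table`` is a two-column TSV path (strain, chemical) or an iterable of
    such pairs.  Chemical nodes are created when absent; duplicate rows are
    idempotent.
    """
    if isinstance(table, (str, Path)):
        rows: list[tuple[str, str]] = []
        with Path(table).open("r", newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) < 2 or not row[0].strip() or not row[1].strip():
                    raise ValueError(f"{table}:{lineno}: expected strain<TAB>chemical")
                rows.append((row[0].strip(), row[1].strip()))
    else:
        rows = list(table)
    for strain, chemical in rows:
        u = _ensure_node(g, (strain, "strain"))
        v = _ensure_node(g, (chemical, "chemical"))
        if not g.has_edge(u, v):
            g.add_edge(
                u, v,
                relation="strain_chemical", weight=1,
                llr=None, significant=None, direction=None,
                provenance=[], citations=[],
            )
    return g


def average_degree(n_nodes: int, n_edges: int) -> float:
    """Mean node degree 2|E|/|V| of an undirected graph (0 for empty graphs)."""
    return 2.0 * n_edges / n_nodes if n_nodes else 0.0


def graph_summary(g: nx.Graph) -> dict:
    """Node/edge counts by type plus the average node degree (and its rounding)."""
    by_type: dict[str, int] = {}
    for _n, data in g.nodes(data=True):
        by_type[data["etype"]] = by_type.get(data["etype"], 0) + 1
    avg = average_degree(g.number_of_nodes(), g.number_of_edges())
    return {
        "node_count": g.number_of_nodes(),
        "node_count_by_type": dict(sorted(by_type.items())),
        "edge_count": g.number_of_edges(),
        "average_degree": avg,
        "average_degree_rounded": int(round(avg)),
    }


def validate_graph(g: nx.Graph) -> None:
    """Check multipartite invariants: no self-edges, admissible types only,
    provenance cardinality consistent with the stored edge data."""
    for u, v, data in g.edges(data=True):
        if u == v:
            raise AssertionError(f"self-edge at {u}")
        tu, tv = g.nodes[u]["etype"], g.nodes[v]["etype"]
        expected = ADMISSIBLE_RELATIONS.get(frozenset((tu, tv)))
        if expected is None or expected != data.get("relation"):
            raise AssertionError(f"inadmissible edge {u} -- {v} ({tu}/{tv}, {data.get('relation')})")
        prov = data.get("provenance", [])
        if data["relation"] != "strain_chemical" and data.get("weight", 0) < len(prov):
            raise AssertionError(f"edge {u}--{v}: weight below provenance cardinality")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    """GraphML export; list-valued provenance becomes a count attribute."""
    h = nx.Graph()
    for n, data in sorted(g.nodes(data=True)):
        h.add_node(n, canonical=data["canonical"], etype=data["etype"], degree=g.degree(n))
    for u, v, data in sorted(g.edges(data=True)):
        h.add_edge(
            u, v,
            relation=data["relation"],
            weight=int(data["weight"]),
            llr=float(data["llr"]) if data.get("llr") is not None else -1.0,
            significant=bool(data.get("significant")),
            direction=data.get("direction") or "",
            provenance_count=len(data.get("provenance", [])),
        )
    nx.write_graphml(h, str(path))


def write_edgelist(g: nx.Graph, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["node_u", "node_v", "relation", "weight", "llr", "significant", "direction"])
        for u, v, data in sorted(g.edges(data=True)):
            w.writerow(
                [
                    u, v, data["relation"], data["weight"],
                    "" if data.get("llr") is None else f"{data['llr']:.6g}",
                    "" if data.get("significant") is None else int(data["significant"]),
                    data.get("direction") or "",
                ]
            )


def write_json_graph(g: nx.Graph, path: str | Path) -> None:
    """Full-fidelity JSON dump including provenance paragraph keys."""
    payload = {
        "graph": dict(g.graph),
        "nodes": [
            {"id": n, **{k: v for k, v in sorted(data.items())}}
            for n, data in sorted(g.nodes(data=True))
        ],
        "edges": [
            {
                "u": u,
                "v": v,
                **{
                    k: (sorted(map(list, v_)) if k == "provenance" else v_)
                    for k, v_ in sorted(data.items())
                },
            }
            for u, v, data in sorted(g.edges(data=True))
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8")


def read_json_graph(path: str | Path) -> nx.Graph:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    g = nx.Graph(**payload.get("graph", {}))
    for node in payload["nodes"]:
        node = dict(node)
        g.add_node(node.pop("id"), **node)
    for edge in payload["edges"]:
        edge = dict(edge)
        u, v = edge.pop("u"), edge.pop("v")
        if "provenance" in edge:
            edge["provenance"] = [tuple(p) for p in edge["provenance"]]
        g.add_edge(u, v, **edge)
    return g
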