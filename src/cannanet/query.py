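"""Subgraph querying: neighborhoods, degree filtering, heatmaps, provenance.

Mirrors the interactive exploration workflow on the full network: query a
set of node names, project the nodes and their neighbors into an induced
subgraph, progressively filter out low-degree nodes until the picture is
human-readable, and recall the supporting paragraphs behind any edge.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .corpus import Document
from .lexicon import normalize_term

__all__ = [
    "Subgraph",
    "QueryError",
    "neighbor_subgraph",
    "filter_by_degree",
    "heatmap_matrix",
    "write_heatmap_csv",
    "recall_provenance",
    "plot_subgraph",
]

log = logging.getLogger(__name__)

NODE_COLORS = {"gene": "green", "chemical": "gold", "property": "royalblue", "strain": "orange"}


class QueryError(KeyError):
    """A query name did not resolve to any graph node."""


@dataclass
class Subgraph:
    """An induced subgraph around a set of anchor (queried) nodes."""

    anchors: frozenset[str]
    graph: nx.Graph
    local_degree: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        missing = [a for a in self.anchors if a not in self.graph and a is not None]
        # anchors may legitimately be filtered out when unprotected
        self.anchors = frozenset(a for a in self.anchors if a not in missing) | frozenset(
            a for a in self.anchors if a in self.graph
        )
        self._recompute()

    def _recompute(self) -> None:
        self.local_degree = {n: d for n, d in self.graph.degree()}

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self):
        return self.graph.edges

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


def _edit_distance(a: str, b: str, cap: int = 3) -> int:
    if abs(len(a) - len(b)) > cap:
        return cap + 1
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def _resolve(g: nx.Graph, name: str) -> list[str]:
    """All node ids whose canonical matches ``name`` (any type)."""
    wanted = normalize_term(name)
    hits = [n for n, data in g.nodes(data=True) if data.get("canonical") == wanted]
    if hits:
        return hits
    near = sorted(
        {
            data["canonical"]
            for _n, data in g.nodes(data=True)
            if _edit_distance(wanted, data["canonical"], cap=2) <= 2
        }
    )
    hint = f"; did you mean: {', '.join(near[:5])}?" if near else ""
    raise QueryError(f"query name {name!r} matches no node{hint}")


def neighbor_subgraph(g: nx.Graph, query: Sequence[str], hops: int = 1) -> Subgraph:
    """Induced subgraph of the queried nodes and their ``hops``-neighborhoods.

    Ambiguous names resolve to every matching type.  Edges are the full
    induced edge set over the selected nodes.
    """
    anchors: set[str] = set()
    for name in query:
        anchors.update(_resolve(g, name))
    nodes = set(anchors)
    frontier = set(anchors)
    for _ in range(max(0, hops)):
        frontier = {nb for n in frontier for nb in g.neighbors(n)} - nodes
        nodes |= frontier
    return Subgraph(anchors=frozenset(anchors), graph=g.subgraph(nodes).copy())


def filter_by_degree(
    s: Subgraph,
    min_degree: int,
    protect_anchors: bool = True,
    iterate: bool = False,
) -> Subgraph:
    """Drop nodes whose *current* local degree is below ``min_degree``.

    Single pass by default: removal decisions use the input subgraph's
    degrees, then dangling edges disappear and degrees are recomputed — so
    surviving nodes' local degrees can shrink, as seen when progressively
    filtering a dense neighborhood.  ``iterate`` repeats to the fixed point
    (k-core-like).  Anchors are kept when ``protect_anchors`` is set.
    """
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    g = s.graph.copy()
    anchors = s.anchors
    while True:
        degrees = dict(g.degree())
        drop = [
            n
            for n, d in degrees.items()
            if d < min_degree and not (protect_anchors and n in anchors)
        ]
        g.remove_nodes_from(drop)
        if not drop or not iterate:
            break
    return Subgraph(anchors=frozenset(a for a in anchors if a in g), graph=g)


def heatmap_matrix(
    s: Subgraph,
    row_type: str,
    col_type: str,
    values: str = "weight",
) -> tuple[np.ndarray, list[str], list[str]]:
    """Edge-value matrix between two node types of a subgraph.

    Rows and columns are the subgraph's nodes of each type, sorted
    lexicographically by canonical name; a cell holds the connecting edge's
    weight (default) or, with ``values='degree'``, the summed local degrees
    of its endpoints; absent edges give 0.
    """
    if row_type == col_type:
        raise ValueError("row_type and col_type must differ")
    if values not in ("weight", "degree"):
        raise ValueError("values must be 'weight' or 'degree'")

    def _of_type(t: str) -> list[str]:
        return sorted(
            (n for n, d in s.graph.nodes(data=True) if d.get("etype") == t),
            key=lambda n: s.graph.nodes[n]["canonical"],
        )

    rows, cols = _of_type(row_type), _of_type(col_type)
    if not rows or not cols:
        missing = row_type if not rows else col_type
        raise ValueError(f"no nodes of type {missing!r} in subgraph")
    M = np.zeros((len(rows), len(cols)))
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            if s.graph.has_edge(r, c):
                if values == "weight":
                    M[i, j] = s.graph.edges[r, c]["weight"]
                else:
                    M[i, j] = s.local_degree[r] + s.local_degree[c]
    row_labels = [s.graph.nodes[n]["canonical"] for n in rows]
    col_labels = [s.graph.nodes[n]["canonical"] for n in cols]
    return M, row_labels, col_labels


def write_heatmap_csv(
    matrix: np.ndarray, row_labels: Sequence[str], col_labels: Sequence[str], path: str | Path
) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["", *col_labels])
        for label, row in zip(row_labels, matrix):
            w.writerow([label, *(int(x) if float(x).is_integer() else x for x in row)])


def recall_provenance(
    g: nx.Graph, edge: tuple[str, str], corpus: Sequence[Document]
) -> list[tuple[str, dict]]:
    """Supporting paragraphs (full text + citation) for one edge, in corpus order.

    Strain edges carry no provenance and return an empty list.  Provenance
    documents missing from the supplied corpus are skipped with a warning.
    """
    u, v = edge
    if not g.has_edge(u, v):
        raise KeyError(f"edge ({u}, {v}) not in graph")
    by_id = {doc.doc_id: doc for doc in corpus}
    out: list[tuple[str, dict]] = []
    for doc_id, para_index in sorted(g.edges[u, v].get("provenance", [])):
        doc = by_id.get(doc_id)
        if doc is None:
            log.warning("provenance document %s missing from corpus", doc_id)
            continue
        para = next((p for p in doc.paragraphs if p.index == para_index), None)
        if para is None:
            log.warning("paragraph (%s, %d) missing from corpus", doc_id, para_index)
            continue
        out.append((para.text, doc.citation))
    return out


def plot_subgraph(s: Subgraph, path: str | Path, seed: int = 0) -> None:
    """Static figure export with the standard type colors and a seeded layout."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = s.graph
    pos = nx.spring_layout(g, seed=seed)
    colors = [NODE_COLORS.get(g.nodes[n].get("etype", ""), "gray") for n in g.nodes]
    fig, ax = plt.subplots(figsize=(8, 8))
    nx.draw_networkx(
        g, pos=pos, ax=ax, node_color=colors, with_labels=True,
        labels={n: g.nodes[n]["canonical"] for n in g.nodes}, font_size=7, node_size=250,
    )
    ax.set_axis_off()
    fig.savefig(str(path), dpi=150, bbox_inches="tight")
    plt.close(fig)
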