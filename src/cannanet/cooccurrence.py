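"""Paragraph-level occurrence and co-occurrence accumulation.

Probabilities downstream are defined at paragraph granularity: ``occ[e]``
counts paragraphs containing entity ``e`` at least once, and ``pair_occ``
counts paragraphs containing both members of an admissible pair.  Mention
multiplicity enters only the edge weight — per co-occurring paragraph, the
product of the two entities' in-paragraph mention counts, summed over
paragraphs.  Only gene–chemical and chemical–property pairs are counted;
strain edges are manual and bypass this module.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .lexicon import Mention

__all__ = [
    "Entity",
    "ContingencyTable",
    "CooccurrenceCounts",
    "relation_for",
    "accumulate",
    "contingency",
    "counts_from_matrix",
]

#: an entity is identified by (canonical, etype); same string may exist per type
Entity = tuple[str, str]

_ADMISSIBLE: dict[frozenset[str], str] = {
    frozenset(("gene", "chemical")): "gene_chemical",
    frozenset(("chemical", "property")): "chemical_property",
}


def relation_for(etype1: str, etype2: str) -> str | None:
    """Relation name for an admissible type pair, else None."""
    return _ADMISSIBLE.get(frozenset((etype1, etype2)))


def pair_key(e1: Entity, e2: Entity) -> tuple[Entity, Entity]:
    """Canonical unordered pair key."""
    return (e1, e2) if e1 <= e2 else (e2, e1)


@dataclass(frozen=True)
class ContingencyTable:
    """Paragraph-level 2x2 presence table for an entity pair.

    k11 = both present, k12 = a only, k21 = g only, k22 = neither;
    cells sum to the number of paragraphs scanned.
    """

    k11: int
    k12: int
    k21: int
    k22: int

    def __post_init__(self) -> None:
        if min(self.k11, self.k12, self.k21, self.k22) < 0:
            raise ValueError("contingency cells must be non-negative")
        if self.N < 1:
            raise ValueError("contingency table requires N >= 1")

    @property
    def N(self) -> int:
        return self.k11 + self.k12 + self.k21 + self.k22

    @property
    def c_a(self) -> int:
        return self.k11 + self.k12

    @property
    def c_g(self) -> int:
        return self.k11 + self.k21

    def transpose(self) -> "ContingencyTable":
        return ContingencyTable(self.k11, self.k21, self.k12, self.k22)


@dataclass
class CooccurrenceCounts:
    """Accumulated paragraph presence counts feeding the association test."""

    N: int = 0
    occ: dict[Entity, int] = field(default_factory=dict)
    pair_occ: dict[tuple[Entity, Entity], int] = field(default_factory=dict)
    pair_weight: dict[tuple[Entity, Entity], int] = field(default_factory=dict)
    pair_paragraphs: dict[tuple[Entity, Entity], set[tuple[str, int]]] = field(
        default_factory=dict
    )

    def entities(self) -> list[Entity]:
        return sorted(self.occ)

    def pairs(self) -> list[tuple[Entity, Entity]]:
        return sorted(self.pair_occ)


def accumulate(counts: CooccurrenceCounts, mentions: Sequence[Mention]) -> CooccurrenceCounts:
    """Fold one paragraph's mentions into the running counts (in place).

    All mentions must share one (doc_id, para_index).  N increments by one;
    each distinct entity's occ increments once; every admissible pair of
    distinct entities updates pair_occ (+1), pair_weight (+ product of the
    two mention counts) and the provenance paragraph set.
    """
    keys = {(m.doc_id, m.para_index) for m in mentions}
    if len(keys) > 1:
        raise ValueError(f"mentions from multiple paragraphs in one call: {sorted(keys)}")
    counts.N += 1
    if not mentions:
        return counts
    para = next(iter(keys))
    by_entity: dict[Entity, int] = {}
    for m in mentions:
        by_entity[m.entity] = by_entity.get(m.entity, 0) + m.count
    for ent in by_entity:
        counts.occ[ent] = counts.occ.get(ent, 0) + 1
    for e1, e2 in combinations(sorted(by_entity), 2):
        if relation_for(e1[1], e2[1]) is None:
            continue
        key = pair_key(e1, e2)
        counts.pair_occ[key] = counts.pair_occ.get(key, 0) + 1
        counts.pair_weight[key] = (
            counts.pair_weight.get(key, 0) + by_entity[e1] * by_entity[e2]
        )
        counts.pair_paragraphs.setdefault(key, set()).add(para)
    return counts


def accumulate_stream(
    tagged_paragraphs: Iterable[Sequence[Mention]],
    counts: CooccurrenceCounts | None = None,
) -> CooccurrenceCounts:
    """Accumulate a whole stream of per-paragraph mention lists."""
    counts = counts if counts is not None else CooccurrenceCounts()
    for mentions in tagged_paragraphs:
        accumulate(counts, mentions)
    return counts


def contingency(counts: CooccurrenceCounts, a: Entity, g: Entity) -> ContingencyTable:
    """2x2 paragraph presence table for entities ``a`` and ``g``."""
    for ent in (a, g):
        if ent not in counts.occ:
            raise KeyError(f"entity {ent} not seen in corpus")
    c_ag = counts.pair_occ.get(pair_key(a, g), 0)
    c_a = counts.occ[a]
    c_g = counts.occ[g]
    return ContingencyTable(
        k11=c_ag,
        k12=c_a - c_ag,
        k21=c_g - c_ag,
        k22=counts.N - c_a - c_g + c_ag,
    )


def counts_from_matrix(
    mention_matrix: np.ndarray,
    entities: Sequence[Entity],
    doc_id: str = "synthetic",
    store_provenance: bool = True,
) -> CooccurrenceCounts:
    """Build counts from a dense (paragraphs x entities) mention-count matrix.

    Equivalent to streaming :func:`accumulate` over the rows but vectorized:
    pair presence counts come from the boolean Gram matrix and pair weights
    from the integer Gram matrix (the per-paragraph product is zero whenever
    either entity is absent, so the matrix product is exactly the summed
    product rule).  Row ``i`` is paragraph ``(doc_id, i)``.
    """
    M = np.asarray(mention_matrix)
    if M.ndim != 2 or M.shape[1] != len(entities):
        raise ValueError("mention_matrix must be (n_paragraphs, n_entities)")
    P = (M > 0).astype(np.int64)
    gram_occ = P.T @ P
    gram_weight = M.T.astype(np.int64) @ M.astype(np.int64)

    counts = CooccurrenceCounts(N=M.shape[0])
    col = {ent: j for j, ent in enumerate(entities)}
    for ent, j in col.items():
        n = int(P[:, j].sum())
        if n:
            counts.occ[ent] = n
    for e1, e2 in combinations(sorted(col), 2):
        if relation_for(e1[1], e2[1]) is None:
            continue
        j1, j2 = col[e1], col[e2]
        c = int(gram_occ[j1, j2])
        if c == 0:
            continue
        key = pair_key(e1, e2)
        counts.pair_occ[key] = c
        counts.pair_weight[key] = int(gram_weight[j1, j2])
        if store_provenance:
            rows = np.nonzero(P[:, j1] & P[:, j2])[0]
            counts.pair_paragraphs[key] = {(doc_id, int(i)) for i in rows}
    return counts


# --- persistence: three TSVs for resumable pipelines -------------------------


def save_counts(counts: CooccurrenceCounts, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with (directory / "entity_counts.tsv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["canonical", "etype", "paragraph_count", "total_paragraphs"])
        for (canonical, etype), c in sorted(counts.occ.items()):
            w.writerow([canonical, etype, c, counts.N])
    with (directory / "pair_counts.tsv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["canonical_1", "etype_1", "canonical_2", "etype_2", "pair_occ", "pair_weight"])
        for (e1, e2) in counts.pairs():
            w.writerow([e1[0], e1[1], e2[0], e2[1], counts.pair_occ[(e1, e2)], counts.pair_weight[(e1, e2)]])
    with (directory / "pair_paragraphs.tsv").open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["canonical_1", "etype_1", "canonical_2", "etype_2", "doc_id", "para_index"])
        for key in counts.pairs():
            (e1, e2) = key
            for doc_id, idx in sorted(counts.pair_paragraphs.get(key, ())):
                w.writerow([e1[0], e1[1], e2[0], e2[1], doc_id, idx])


def load_counts(directory: str | Path) -> CooccurrenceCounts:
    directory = Path(directory)
    counts = CooccurrenceCounts()
    with (directory / "entity_counts.tsv").open("r", newline="", encoding="utf-8") as fh:
        for row in list(csv.reader(fh, delimiter="\t"))[1:]:
            canonical, etype, c, n = row
            counts.occ[(canonical, etype)] = int(c)
            counts.N = int(n)
    with (directory / "pair_counts.tsv").open("r", newline="", encoding="utf-8") as fh:
        for row in list(csv.reader(fh, delimiter="\t"))[1:]:
            key = pair_key((row[0], row[1]), (row[2], row[3]))
            counts.pair_occ[key] = int(row[4])
            counts.pair_weight[key] = int(row[5])
    with (directory / "pair_paragraphs.tsv").open("r", newline="", encoding="utf-8") as fh:
        for row in list(csv.reader(fh, delimiter="\t"))[1:]:
            key = pair_key((row[0], row[1]), (row[2], row[3]))
            counts.pair_paragraphs.setdefault(key, set()).add((row[4], int(row[5])))
    return counts
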