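"""Synthetic corpora with known ground truth for end-to-end validation.

Generates documents whose paragraphs contain planted entity mentions with
controlled marginal rates, controlled pairwise dependence, and known
mention-count distributions, embedded in filler text that is disjoint from
every lexicon surface (so matcher precision is exactly 1 by construction).
Every pipeline stage — tagging, counting, testing, graph building — can be
checked against the generator's exact ground truth without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .corpus import Document, Paragraph
from .cooccurrence import Entity, pair_key, relation_for
from .lexicon import Lexicon, LexiconEntry, normalize_term

__all__ = ["SyntheticSpec", "GroundTruth", "generate", "generate_presence", "planted_recovery_report"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator parameters; generation is a pure function of (spec, seed).

    ``entities`` are (canonical, etype, per-paragraph base rate) triples;
    ``dependent_pairs`` are (canonical_1, canonical_2, joint_boost) with the
    joint inclusion probability raised to boost·p1·p2 (capped at min(p1,p2)).
    Mention counts per included entity follow either ``("fixed", k)`` or a
    shifted geometric ``("geometric", q)`` on {1, 2, 3, ...}.
    """

    entities: tuple[tuple[str, str, float], ...]
    dependent_pairs: tuple[tuple[str, str, float], ...] = ()
    n_docs: int = 10
    paras_per_doc: int | tuple[int, int] = 20
    mention_count_model: tuple = ("geometric", 0.5)
    filler_vocab_size: int = 50
    filler_tokens_per_paragraph: int = 25
    adversarial: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        names = [c for c, _t, _r in self.entities]
        if len(set(names)) != len(names):
            raise ValueError("duplicate entity canonicals in spec")
        for c, t, r in self.entities:
            if not (0.0 < r <= 1.0):
                raise ValueError(f"base rate for {c!r} must lie in (0, 1], got {r}")
            if t not in ("gene", "chemical", "property", "strain"):
                raise ValueError(f"unknown entity type {t!r}")
            if normalize_term(c).startswith("filler"):
                raise ValueError("entity names must not collide with filler vocabulary")
        etype = {c: t for c, t, _ in self.entities}
        rate = {c: r for c, _, r in self.entities}
        in_pair: set[str] = set()
        for a, b, boost in self.dependent_pairs:
            if a not in etype or b not in etype:
                raise ValueError(f"dependent pair ({a}, {b}) references unknown entity")
            if relation_for(etype[a], etype[b]) is None:
                raise ValueError(f"dependent pair ({a}, {b}) is not an admissible type pair")
            if boost <= 1.0:
                raise ValueError("joint_boost must exceed 1")
            if a in in_pair or b in in_pair:
                raise ValueError("each entity may appear in at most one dependent pair")
            in_pair.update((a, b))
            if self.joint_probability(a, b) > min(rate[a], rate[b]) + 1e-12:
                raise ValueError(f"joint probability for ({a}, {b}) exceeds a marginal rate")
        kind = self.mention_count_model[0]
        if kind == "fixed":
            if int(self.mention_count_model[1]) < 1:
                raise ValueError("fixed mention count must be >= 1")
        elif kind == "geometric":
            q = float(self.mention_count_model[1])
            if not (0.0 < q <= 1.0):
                raise ValueError("geometric parameter must lie in (0, 1]")
        else:
            raise ValueError(f"unknown mention_count_model {kind!r}")

    def joint_probability(self, a: str, b: str) -> float:
        """Theoretical P(both present in a paragraph) for any entity pair."""
        rate = {c: r for c, _, r in self.entities}
        for x, y, boost in self.dependent_pairs:
            if {x, y} == {a, b}:
                return min(boost * rate[x] * rate[y], min(rate[x], rate[y]))
        return rate[a] * rate[b]

    @property
    def entity_keys(self) -> list[Entity]:
        return [(normalize_term(c), t) for c, t, _ in self.entities]


@dataclass
class GroundTruth:
    """Exact per-paragraph mention counts and the planted dependence structure."""

    spec: SyntheticSpec
    entities: list[Entity]
    mention_counts: np.ndarray  # (n_paragraphs, n_entities) ints
    paragraph_keys: list[tuple[str, int]]
    joint_probs: dict[tuple[Entity, Entity], float] = field(default_factory=dict)

    @property
    def presence(self) -> np.ndarray:
        return self.mention_counts > 0

    def dependent_pair_keys(self) -> set[tuple[Entity, Entity]]:
        etype = {normalize_term(c): t for c, t, _ in self.spec.entities}
        return {
            pair_key((normalize_term(a), etype[normalize_term(a)]),
                     (normalize_term(b), etype[normalize_term(b)]))
            for a, b, _ in self.spec.dependent_pairs
        }

    def admissible_pair_keys(self) -> set[tuple[Entity, Entity]]:
        from itertools import combinations

        return {
            pair_key(e1, e2)
            for e1, e2 in combinations(sorted(self.entities), 2)
            if relation_for(e1[1], e2[1]) is not None
        }

    def pair_weight(self, e1: Entity, e2: Entity) -> int:
        j1 = self.entities.index(e1)
        j2 = self.entities.index(e2)
        return int(self.mention_counts[:, j1] @ self.mention_counts[:, j2])


def _n_paragraphs(spec: SyntheticSpec, rng: np.random.Generator) -> list[int]:
    if isinstance(spec.paras_per_doc, tuple):
        lo, hi = spec.paras_per_doc
        return [int(rng.integers(lo, hi + 1)) for _ in range(spec.n_docs)]
    return [int(spec.paras_per_doc)] * spec.n_docs


def _sample_counts(spec: SyntheticSpec, presence: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    kind, param = spec.mention_count_model[0], spec.mention_count_model[1]
    counts = np.zeros(presence.shape, dtype=np.int64)
    idx = np.nonzero(presence)
    if kind == "fixed":
        counts[idx] = int(param)
    else:  # shifted geometric on {1, 2, ...}
        counts[idx] = rng.geometric(float(param), size=len(idx[0]))
    return counts


def generate_presence(
    spec: SyntheticSpec, rng: np.random.Generator | None = None
) -> GroundTruth:
    """Sample the presence/mention-count structure without rendering text.

    This is the generator's core; :func:`generate` renders the same draw as
    documents with filler prose.  Independent entities are Bernoulli at their
    base rate per paragraph; a dependent pair is drawn from the 2x2 joint
    distribution with the boosted joint probability and unchanged marginals.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    per_doc = _n_paragraphs(spec, rng)
    n_paras = sum(per_doc)
    ents = spec.entity_keys
    names = [c for c, _t, _r in spec.entities]
    rates = np.array([r for _c, _t, r in spec.entities])
    col = {n: j for j, n in enumerate(names)}

    presence = np.zeros((n_paras, len(ents)), dtype=bool)
    paired_cols: set[int] = set()
    joint_probs: dict[tuple[Entity, Entity], float] = {}
    for a, b, _boost in spec.dependent_pairs:
        ja, jb = col[a], col[b]
        paired_cols.update((ja, jb))
        p1, p2 = rates[ja], rates[jb]
        p12 = spec.joint_probability(a, b)
        probs = [p12, p1 - p12, p2 - p12, 1.0 - p1 - p2 + p12]
        draw = rng.choice(4, size=n_paras, p=probs)
        presence[:, ja] = (draw == 0) | (draw == 1)
        presence[:, jb] = (draw == 0) | (draw == 2)
        joint_probs[pair_key(ents[ja], ents[jb])] = p12
    free = [j for j in range(len(ents)) if j not in paired_cols]
    if free:
        presence[:, free] = rng.random((n_paras, len(free))) < rates[free]

    counts = _sample_counts(spec, presence, rng)
    keys: list[tuple[str, int]] = []
    for d, n in enumerate(per_doc):
        doc_id = f"syn{d:04d}"
        keys.extend((doc_id, i) for i in range(n))
    return GroundTruth(
        spec=spec,
        entities=ents,
        mention_counts=counts,
        paragraph_keys=keys,
        joint_probs=joint_probs,
    )


def build_lexicon(spec: SyntheticSpec) -> Lexicon:
    """Lexicon whose surfaces are exactly the spec's entity canonicals."""
    return Lexicon(
        LexiconEntry(surface=normalize_term(c), canonical=normalize_term(c), etype=t)
        for c, t, _r in spec.entities
    )


def _filler_vocab(spec: SyntheticSpec, lexicon: Lexicon) -> list[str]:
    vocab = [f"filler{i:04d}" for i in range(spec.filler_vocab_size)]
    if spec.adversarial:
        # near-miss strings: surface tokens with a trailing character, and
        # multi-word prefixes that are not themselves surfaces — these must
        # never match, exercising the longest-match boundary
        surfaces = {e.surface for e in lexicon}
        extras: list[str] = []
        for s in sorted(surfaces):
            toks = s.split()
            extras.append(toks[0] + "x")
            if len(toks) > 1 and " ".join(toks[:-1]) not in surfaces:
                extras.append(" ".join(toks[:-1]) + "y")
        vocab.extend(x for x in extras if x not in surfaces)
    return vocab


def generate(spec: SyntheticSpec) -> tuple[list[Document], GroundTruth]:
    """Render a full synthetic corpus plus its exact ground truth.

    Deterministic in ``spec`` (including ``spec.seed``): the same spec
    yields a byte-identical corpus.  Each included entity's surface is
    embedded ``count`` times among shuffled filler tokens.
    """
    rng = np.random.default_rng(spec.seed)
    truth = generate_presence(spec, rng)
    lexicon = build_lexicon(spec)
    filler = _filler_vocab(spec, lexicon)
    surfaces = [normalize_term(c) for c, _t, _r in spec.entities]

    docs: dict[str, Document] = {}
    for row, (doc_id, idx) in enumerate(truth.paragraph_keys):
        units: list[str] = []
        for j, surface in enumerate(surfaces):
            units.extend([surface] * int(truth.mention_counts[row, j]))
        n_fill = max(spec.filler_tokens_per_paragraph, 1)
        units.extend(rng.choice(filler, size=n_fill))
        order = rng.permutation(len(units))
        text = " ".join(units[i] for i in order)
        doc = docs.get(doc_id)
        if doc is None:
            doc = Document(
                doc_id=doc_id,
                title=f"a synthetic document from the generator ({doc_id})",
                abstract="",
                meta={"journal": "synthetic", "doi": f"10.0000/{doc_id}"},
            )
            docs[doc_id] = doc
        doc.paragraphs.append(Paragraph(doc_id, idx, text))
    return list(docs.values()), truth


def planted_recovery_report(truth: GroundTruth, results: Sequence) -> dict:
    """Score pipeline output against the generator's dependence structure.

    ``results`` are :class:`~cannanet.association.AssociationResult` records.
    Sensitivity is the fraction of planted dependent pairs flagged
    significant; the false-positive rate is the fraction of independent
    admissible pairs flagged; ``weight_exactness`` requires every scored
    pair's weight to equal the ground-truth sum of mention-count products.
    """
    planted = truth.dependent_pair_keys()
    admissible = truth.admissible_pair_keys()
    independent = admissible - planted
    significant = {r.pair for r in results if r.significant}
    weight_ok = all(r.weight == truth.pair_weight(*r.pair) for r in results)
    return {
        "sensitivity": (
            len(planted & significant) / len(planted) if planted else float("nan")
        ),
        "false_positive_rate": (
            len(independent & significant) / len(independent) if independent else 0.0
        ),
        "weight_exactness": weight_ok,
        "n_planted": len(planted),
        "n_independent": len(independent),
    }
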