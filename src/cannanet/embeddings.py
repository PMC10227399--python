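"""Skip-gram word embeddings and similarity-based lexicon expansion.

Trains word2vec-style skip-gram vectors with negative sampling (SGNS) on the
corpus, then expands a manually curated seed list of therapeutic-property
phrases by cosine-similarity neighborhood search.  Expansion output is a
review file for human curation, never auto-ingested into the lexicon.

The trainer is a compact single-threaded numpy implementation: one worker and
a fixed seed make training bit-reproducible, which multi-worker trainers do
not guarantee.  Frequent bigrams are merged into single ``a_b`` tokens before
training so multi-word properties (e.g. "anti inflammatory") can embed.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .corpus import Document, paragraph_stream
from .lexicon import _tokenize, normalize_term

__all__ = [
    "SkipgramParams",
    "EmbeddingModel",
    "ExpansionResult",
    "cosine_similarity",
    "train_skipgram",
    "expand_terms",
    "merge_bigrams",
]


@dataclass(frozen=True)
class SkipgramParams:
    """Skip-gram hyperparameters; all exposed in the pipeline config."""

    dim: int = 100
    window: int = 5
    min_count: int = 5
    epochs: int = 5
    seed: int = 0
    negative: int = 5
    alpha: float = 0.025  # initial learning rate, linearly decayed
    min_alpha: float = 1e-4
    bigram_min_count: int = 25  # joint frequency above which bigrams merge

    def validate(self) -> None:
        if self.dim < 2 or self.window < 1 or self.min_count < 1 or self.epochs < 1:
            raise ValueError("invalid skip-gram parameters: need dim>=2, window>=1, min_count>=1, epochs>=1")


@dataclass(frozen=True)
class ExpansionResult:
    """Accepted neighbors for one seed term, sorted by descending similarity."""

    seed: str
    neighbors: tuple[tuple[str, float], ...]


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """u·v / (‖u‖‖v‖), in [-1, 1].  Zero vectors are rejected, not mapped to 0."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.clip(u @ v / (nu * nv), -1.0, 1.0))


def merge_bigrams(sentences: list[list[str]], min_count: int) -> list[list[str]]:
    """Merge adjacent token pairs seen at least ``min_count`` times into ``a_b``.

    Single greedy left-to-right pass; a token consumed by one merge cannot
    start another.
    """
    pair_counts: Counter[tuple[str, str]] = Counter()
    for sent in sentences:
        pair_counts.update(zip(sent, sent[1:]))
    keep = {p for p, c in pair_counts.items() if c >= min_count}
    if not keep:
        return sentences
    out: list[list[str]] = []
    for sent in sentences:
        merged: list[str] = []
        i = 0
        while i < len(sent):
            if i + 1 < len(sent) and (sent[i], sent[i + 1]) in keep:
                merged.append(f"{sent[i]}_{sent[i + 1]}")
                i += 2
            else:
                merged.append(sent[i])
                i += 1
        out.append(merged)
    return out


@dataclass
class EmbeddingModel:
    """Vocabulary plus one fixed-dimension vector per term."""

    terms: list[str]
    vectors: np.ndarray  # (V, dim)
    params: SkipgramParams
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        if self.vectors.shape[0] != len(self.terms):
            raise ValueError("one vector per term required")
        self.index = {t: i for i, t in enumerate(self.terms)}

    def __contains__(self, term: str) -> bool:
        return term in self.index

    def vector(self, term: str) -> np.ndarray:
        return self.vectors[self.index[term]]

    def most_similar(
        self, term: str, top_k: int = 10, threshold: float = -1.0
    ) -> list[tuple[str, float]]:
        """The ``top_k`` nearest vocabulary terms by cosine, above ``threshold``."""
        v = self.vector(term)
        norms = np.linalg.norm(self.vectors, axis=1)
        nv = np.linalg.norm(v)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = self.vectors @ v / (norms * nv)
        sims = np.nan_to_num(sims, nan=-1.0)
        order = np.argsort(-sims, kind="stable")
        out: list[tuple[str, float]] = []
        for i in order:
            if self.terms[i] == term:
                continue
            s = float(sims[i])
            if s < threshold:
                break
            out.append((self.terms[i], s))
            if len(out) >= top_k:
                break
        return out

    def save(self, path: str | Path) -> None:
        """word2vec text format: header line, then term + dim floats per line."""
        path = Path(path)
        with path.open("w", encoding="utf-8") as fh:
            fh.write(f"{len(self.terms)} {self.vectors.shape[1]}\n")
            for term, vec in zip(self.terms, self.vectors):
                fh.write(term + " " + " ".join(f"{x:.8g}" for x in vec) + "\n")

    @classmethod
    def load(cls, path: str | Path, params: SkipgramParams | None = None) -> "EmbeddingModel":
        path = Path(path)
        with path.open("r", encoding="utf-8") as fh:
            header = fh.readline().split()
            n, dim = int(header[0]), int(header[1])
            terms: list[str] = []
            rows = np.empty((n, dim))
            for i in range(n):
                parts = fh.readline().rstrip("\n").split(" ")
                terms.append(parts[0])
                rows[i] = [float(x) for x in parts[1 : dim + 1]]
        return cls(terms, rows, params or SkipgramParams(dim=dim))


def corpus_sentences(docs: Sequence[Document], include_abstract: bool = True) -> list[list[str]]:
    """Tokenized training sentences: one per paragraph (+ optional abstract)."""
    return [
        _tokenize(p.text)
        for p in paragraph_stream(docs, include_abstract=include_abstract)
    ]


def train_skipgram(
    docs: Sequence[Document] | list[list[str]],
    params: SkipgramParams = SkipgramParams(),
) -> EmbeddingModel:
    """Train SGNS vectors on a corpus (or pre-tokenized sentences).

    Deterministic for a given (corpus, seed): sampling of window sizes and
    negatives comes from one seeded generator and updates run on one thread.
    Raises if ``min_count`` empties the vocabulary.
    """
    params.validate()
    if docs and isinstance(docs[0], Document):
        sentences = corpus_sentences(docs)  # type: ignore[arg-type]
    else:
        sentences = [list(s) for s in docs]  # type: ignore[union-attr]
    sentences = merge_bigrams(sentences, params.bigram_min_count)

    freq = Counter(tok for sent in sentences for tok in sent)
    vocab = sorted(t for t, c in freq.items() if c >= params.min_count)
    if not vocab:
        raise ValueError(
            f"min_count={params.min_count} leaves an empty vocabulary "
            f"(max term frequency is {max(freq.values(), default=0)}); lower min_count"
        )
    index = {t: i for i, t in enumerate(vocab)}
    V, dim = len(vocab), params.dim

    # unigram^0.75 noise distribution for negative sampling
    counts = np.array([freq[t] for t in vocab], dtype=float)
    noise = counts**0.75
    noise /= noise.sum()

    rng = np.random.default_rng(params.seed)
    w_in = (rng.random((V, dim)) - 0.5) / dim
    w_out = np.zeros((V, dim))

    encoded = [np.array([index[t] for t in sent if t in index], dtype=np.int64) for sent in sentences]
    encoded = [s for s in encoded if len(s) >= 2]
    total_words = sum(len(s) for s in encoded) * params.epochs
    if total_words == 0:
        raise ValueError("no trainable sentences (need >= 2 in-vocabulary tokens per sentence)")

    processed = 0
    k = params.negative
    for _epoch in range(params.epochs):
        for sent in encoded:
            L = len(sent)
            reduced = rng.integers(1, params.window + 1, size=L)
            negs = rng.choice(V, size=(L, 2 * params.window * k), p=noise)
            for pos in range(L):
                center = sent[pos]
                b = reduced[pos]
                lo, hi = max(0, pos - b), min(L, pos + b + 1)
                ctx = np.concatenate((sent[lo:pos], sent[pos + 1 : hi]))
                ctx = ctx[ctx != center]
                if ctx.size == 0:
                    processed += 1
                    continue
                lr = max(
                    params.min_alpha,
                    params.alpha * (1.0 - processed / total_words),
                )
                targets = np.concatenate((ctx, negs[pos, : ctx.size * k]))
                labels = np.zeros(targets.size)
                labels[: ctx.size] = 1.0
                v = w_in[center]
                u = w_out[targets]
                scores = u @ v
                sig = 1.0 / (1.0 + np.exp(-scores))
                g = (labels - sig) * lr
                np.add.at(w_out, targets, np.outer(g, v))
                w_in[center] = v + g @ u
                processed += 1
    return EmbeddingModel(vocab, w_in, params)


def _as_vocab_term(seed: str) -> str:
    """Normalized seed in the trainer's token space (bigrams joined with _)."""
    return "_".join(normalize_term(seed).split())


def _as_phrase(term: str) -> str:
    return term.replace("_", " ")


def expand_terms(
    seeds: Iterable[str],
    model: EmbeddingModel,
    threshold: float = 0.7,
    top_k: int = 10,
) -> tuple[list[ExpansionResult], list[str], list[str]]:
    """Expand a seed term list by embedding-neighborhood search.

    For every seed present in the vocabulary, collect the at most ``top_k``
    nearest terms with cosine similarity >= ``threshold``.  Returns
    ``(results, absent_seeds, merged_list)`` where ``merged_list`` is the
    deduplicated union of seeds and accepted neighbors (a review list —
    acceptance into the lexicon stays a human step).  Absent seeds are
    reported, never silently dropped.
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    results: list[ExpansionResult] = []
    absent: list[str] = []
    merged: dict[str, None] = {}
    for raw_seed in seeds:
        phrase = normalize_term(raw_seed)
        if not phrase:
            continue
        merged.setdefault(phrase)
        term = _as_vocab_term(raw_seed)
        if term not in model:
            absent.append(phrase)
            continue
        neighbors = tuple(
            (nb, sim) for nb, sim in model.most_similar(term, top_k=top_k, threshold=threshold)
        )
        results.append(ExpansionResult(seed=phrase, neighbors=neighbors))
        for nb, _sim in neighbors:
            merged.setdefault(_as_phrase(nb))
    return results, absent, list(merged)


def write_expansion_report(
    results: Sequence[ExpansionResult], absent: Sequence[str], path: str | Path
) -> None:
    """TSV review file: seed, neighbor, similarity ('-' rows for absent seeds)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        fh.write("seed\tneighbor\tsimilarity\n")
        for res in results:
            for nb, sim in res.neighbors:
                fh.write(f"{res.seed}\t{_as_phrase(nb)}\t{sim:.4f}\n")
        for seed in absent:
            fh.write(f"{seed}\t-\tabsent_from_vocabulary\n")
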