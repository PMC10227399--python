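"""Entity lexicons and dictionary-based paragraph tagging.

Entities come in four types — gene, chemical, therapeutic property, strain —
each with one or more surface forms mapping to a canonical name.  The default
tagger is a greedy longest-match dictionary matcher over normalized token
sequences; external model taggers (e.g. a bioNER model) plug in through
:func:`external_tagger_adapter` and produce the same :class:`Mention` records.
"""

from __future__ import annotations

import csv
import re
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Sequence

from .corpus import Paragraph

__all__ = [
    "ETYPES",
    "LexiconEntry",
    "Mention",
    "Lexicon",
    "LexiconError",
    "normalize_term",
    "load_lexicon",
    "match_entities",
    "external_tagger_adapter",
]

ETYPES = ("gene", "chemical", "property", "strain")
# Tie-break priority for equal-length matches: genes are the rarest type.
_ETYPE_PRIORITY = {t: i for i, t in enumerate(ETYPES)}


class LexiconError(ValueError):
    """Raised for malformed lexicon files or inconsistent entries."""


_PUNCT_STRIP_RE = re.compile(r"^[\W_]+|[\W_]+$")
_HYPHEN_WS_RE = re.compile(r"[-‐-―_\s]+")


def normalize_term(raw: str) -> str:
    """Canonical match form of a term.

    Lowercases, strips leading/trailing punctuation, and collapses internal
    hyphens/underscores/whitespace runs to single spaces.  Idempotent.

    >>> normalize_term("Delta-9-Tetrahydrocannabinol")
    'delta 9 tetrahydrocannabinol'
    """
    s = raw.lower()
    s = _HYPHEN_WS_RE.sub(" ", s)
    parts = [_PUNCT_STRIP_RE.sub("", tok) for tok in s.split()]
    return " ".join(p for p in parts if p)


@dataclass(frozen=True)
class LexiconEntry:
    """One surface form of one canonical entity."""

    surface: str
    canonical: str
    etype: str

    def __post_init__(self) -> None:
        if self.etype not in ETYPES:
            raise LexiconError(f"unknown entity type {self.etype!r}")
        if not self.surface:
            raise LexiconError("empty surface form after normalization")


@dataclass(frozen=True)
class Mention:
    """Counted occurrences of one canonical entity in one paragraph."""

    canonical: str
    etype: str
    doc_id: str
    para_index: int
    count: int

    @property
    def entity(self) -> tuple[str, str]:
        return (self.canonical, self.etype)


class Lexicon:
    """A set of :class:`LexiconEntry` with a token-sequence match index."""

    def __init__(self, entries: Iterable[LexiconEntry] = ()) -> None:
        self._by_key: dict[tuple[str, str], LexiconEntry] = {}
        # first token -> [(token tuple, entry)], for the greedy matcher
        self._index: dict[str, list[tuple[tuple[str, ...], LexiconEntry]]] = defaultdict(list)
        self.max_surface_len = 0
        for e in entries:
            self.add(e)

    def add(self, entry: LexiconEntry) -> None:
        key = (entry.surface, entry.etype)
        existing = self._by_key.get(key)
        if existing is not None:
            if existing.canonical != entry.canonical:
                raise LexiconError(
                    f"surface {entry.surface!r} ({entry.etype}) maps to conflicting "
                    f"canonicals {existing.canonical!r} and {entry.canonical!r}"
                )
            return
        self._by_key[key] = entry
        toks = tuple(entry.surface.split())
        self._index[toks[0]].append((toks, entry))
        self.max_surface_len = max(self.max_surface_len, len(toks))

    def __len__(self) -> int:
        return len(self._by_key)

    def __iter__(self):
        return iter(self._by_key.values())

    def entries(self) -> list[LexiconEntry]:
        return sorted(self._by_key.values(), key=lambda e: (e.etype, e.surface))

    def canonical_for(self, surface: str, etype: str) -> str | None:
        e = self._by_key.get((normalize_term(surface), etype))
        return e.canonical if e else None

    def candidates_at(self, first_token: str):
        return self._index.get(first_token, ())

    def merge(self, other: "Lexicon") -> "Lexicon":
        merged = Lexicon(self._by_key.values())
        for e in other:
            merged.add(e)
        return merged


def load_lexicon(path: str | Path, header: bool = False) -> Lexicon:
    """Load a TSV lexicon with columns surface, canonical, etype.

    Surfaces and canonicals pass through :func:`normalize_term`.  Unknown
    entity types and conflicting duplicate surfaces raise
    :class:`LexiconError` with the offending line number.
    """
    path = Path(path)
    lex = Lexicon()
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for lineno, row in enumerate(reader, start=1):
            if header and lineno == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 3:
                raise LexiconError(f"{path}:{lineno}: expected 3 columns, got {len(row)}")
            surface, canonical, etype = (c.strip() for c in row[:3])
            if etype not in ETYPES:
                raise LexiconError(
                    f"{path}:{lineno}: unknown entity type {etype!r} "
                    f"(expected one of {', '.join(ETYPES)})"
                )
            try:
                lex.add(
                    LexiconEntry(
                        surface=normalize_term(surface),
                        canonical=normalize_term(canonical),
                        etype=etype,
                    )
                )
            except LexiconError as exc:
                raise LexiconError(f"{path}:{lineno}: {exc}") from exc
    return lex


def _tokenize(text: str) -> list[str]:
    """Paragraph tokenization mirroring normalize_term at token level."""
    s = _HYPHEN_WS_RE.sub(" ", text.lower())
    toks = [_PUNCT_STRIP_RE.sub("", t) for t in s.split()]
    return [t for t in toks if t]


def match_entities(
    paragraph: Paragraph,
    lexicon: Lexicon,
    return_spans: bool = False,
) -> list[Mention] | tuple[list[Mention], list[tuple[int, int]]]:
    """Tag a paragraph by greedy longest-match dictionary lookup.

    Scans the normalized token sequence left to right; at each position the
    longest matching surface wins (ties between types broken by the fixed
    priority gene > chemical > property > strain), and tokens consumed by a
    match cannot contribute to another.  Returns one :class:`Mention` per
    (canonical, etype) with the aggregated non-overlapping match count.

    ``return_spans`` additionally returns the matched token spans, for
    overlap auditing.
    """
    tokens = _tokenize(paragraph.text)
    counts: dict[tuple[str, str], int] = defaultdict(int)
    spans: list[tuple[int, int]] = []
    i = 0
    n = len(tokens)
    while i < n:
        best: LexiconEntry | None = None
        best_len = 0
        for toks, entry in lexicon.candidates_at(tokens[i]):
            L = len(toks)
            if L > n - i or L < best_len:
                continue
            if tuple(tokens[i : i + L]) == toks:
                if L > best_len or (
                    L == best_len
                    and best is not None
                    and _ETYPE_PRIORITY[entry.etype] < _ETYPE_PRIORITY[best.etype]
                ):
                    best, best_len = entry, L
        if best is not None:
            counts[(best.canonical, best.etype)] += 1
            spans.append((i, i + best_len))
            i += best_len
        else:
            i += 1
    mentions = [
        Mention(canonical, etype, paragraph.doc_id, paragraph.index, c)
        for (canonical, etype), c in sorted(counts.items())
    ]
    if return_spans:
        return mentions, spans
    return mentions


class TaggerError(RuntimeError):
    """An external tagger failed on a paragraph."""


def external_tagger_adapter(
    tag_fn: Callable[[Paragraph], Iterable[tuple]],
    lexicon: Lexicon | None = None,
) -> Callable[[Paragraph], list[Mention]]:
    """Wrap an external named-entity tagger as a drop-in :class:`Mention` source.

    ``tag_fn`` yields ``(surface, etype)`` or ``(surface, etype, start, end)``
    tuples for a paragraph.  Surfaces are normalized and resolved to lexicon
    canonicals where possible; unknown surfaces become their own canonical.
    Spans with character positions are deduplicated by position, so a tagger
    emitting the same span twice counts it once.
    """

    def tagger(paragraph: Paragraph) -> list[Mention]:
        try:
            raw = list(tag_fn(paragraph))
        except Exception as exc:  # noqa: BLE001 - re-raise with context
            raise TaggerError(
                f"external tagger failed on paragraph {paragraph.key}: {exc}"
            ) from exc
        counts: dict[tuple[str, str], int] = defaultdict(int)
        seen_spans: set[tuple[int, int]] = set()
        for item in raw:
            if len(item) == 4:
                surface, etype, start, end = item
                if (start, end) in seen_spans:
                    continue
                seen_spans.add((start, end))
            else:
                surface, etype = item[0], item[1]
            if etype not in ETYPES:
                raise TaggerError(
                    f"external tagger returned unknown entity type {etype!r} "
                    f"for paragraph {paragraph.key}"
                )
            norm = normalize_term(surface)
            if not norm:
                continue
            canonical = None
            if lexicon is not None:
                canonical = lexicon.canonical_for(norm, etype)
            counts[(canonical or norm, etype)] += 1
        return [
            Mention(canonical, etype, paragraph.doc_id, paragraph.index, c)
            for (canonical, etype), c in sorted(counts.items())
        ]

    return tagger


def dictionary_tagger(lexicon: Lexicon) -> Callable[[Paragraph], list[Mention]]:
    """The default tagger: :func:`match_entities` bound to a lexicon."""

    def tagger(paragraph: Paragraph) -> list[Mention]:
        return match_entities(paragraph, lexicon)

    return tagger
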