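"""Corpus ingestion: JATS/PMC-style XML parsing, language filtering, JSONL persistence.

A corpus is an ordered collection of :class:`Document` objects; the unit of
downstream co-occurrence analysis is the :class:`Paragraph`.  Full-text XML is
read with lxml; only a small JATS subset is interpreted (``article-title``,
``abstract//p``, ``body//p``) and all inline markup is flattened to text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

from lxml import etree

__all__ = [
    "Document",
    "Paragraph",
    "CorpusError",
    "parse_pmc_xml",
    "is_english",
    "read_corpus",
    "write_corpus",
    "paragraph_stream",
]

# Function words frequent in English running text.  Deliberately excludes
# forms shared with other major European languages (e.g. German "die",
# "das", "von", "auf") so that the ratio heuristic separates languages.
ENGLISH_STOPWORDS = frozenset(
    """
    the a an and or but if then than because while of to in on at by for
    with about against between into through during before after above
    below from up down out off over under again further once here there
    when where why how all any both each few more most other some such no
    nor not only own same so too very can will just should now is are was
    were be been being have has had having do does did doing would could
    might must shall may it its itself this that these those they them
    their theirs themselves he him his she her hers we us our ours you
    your yours i me my mine which who whom what as
    """.split()
)

_WS_RE = re.compile(r"\s+")


def _collapse_ws(text: str) -> str:
    return _WS_RE.sub(" ", text).strip()


class CorpusError(ValueError):
    """Raised for malformed corpus inputs (XML, JSONL, duplicate ids)."""


@dataclass(frozen=True)
class Paragraph:
    """One body paragraph of one document; the co-occurrence unit."""

    doc_id: str
    index: int
    text: str

    @property
    def key(self) -> tuple[str, int]:
        return (self.doc_id, self.index)


@dataclass
class Document:
    """A full-text article split into ordered paragraphs plus metadata."""

    doc_id: str
    title: str
    abstract: str = ""
    paragraphs: list[Paragraph] = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise CorpusError("Document requires a non-empty doc_id")
        self.meta.setdefault("authors", [])
        self.meta.setdefault("journal", "")
        self.meta.setdefault("pub_date", "")
        self.meta.setdefault("doi", "")

    @property
    def citation(self) -> dict:
        """Citation metadata snapshot attached to edge provenance."""
        return {
            "doc_id": self.doc_id,
            "title": self.title,
            "authors": list(self.meta.get("authors", [])),
            "journal": self.meta.get("journal", ""),
            "pub_date": self.meta.get("pub_date", ""),
            "doi": self.meta.get("doi", ""),
        }

    def to_record(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "title": self.title,
            "abstract": self.abstract,
            "paragraphs": [p.text for p in self.paragraphs],
            "meta": self.meta,
        }

    @classmethod
    def from_record(cls, rec: dict) -> "Document":
        doc = cls(
            doc_id=rec["doc_id"],
            title=rec.get("title", ""),
            abstract=rec.get("abstract", ""),
            meta=dict(rec.get("meta", {})),
        )
        doc.paragraphs = [
            Paragraph(doc.doc_id, i, _collapse_ws(t))
            for i, t in enumerate(rec.get("paragraphs", []))
            if _collapse_ws(t)
        ]
        return doc


def _text_of(elem) -> str:
    """All descendant text of an element, inline markup flattened."""
    return _collapse_ws("".join(elem.itertext()))


def parse_pmc_xml(xml_text: str | bytes, doc_id: str = "") -> Document:
    """Parse one JATS/PMC-style XML article into a :class:`Document`.

    Body ``<p>`` elements become paragraphs in document order; abstract
    ``<p>`` elements are concatenated into the abstract field; unknown
    elements are ignored.  Missing metadata fields become empty strings.

    Raises
    ------
    CorpusError
        If the XML is malformed or contains no title element.
    """
    if isinstance(xml_text, str):
        xml_text = xml_text.encode("utf-8")
    try:
        root = etree.fromstring(xml_text)
    except etree.XMLSyntaxError as exc:
        raise CorpusError(f"malformed XML for document {doc_id or '<unnamed>'}: {exc}") from exc

    title_el = root.find(".//article-title")
    if title_el is None:
        title_el = root.find(".//title")
    if title_el is None:
        raise CorpusError(f"document {doc_id or '<unnamed>'} has no title element")
    title = _text_of(title_el)

    abstract_parts = [_text_of(p) for p in root.iterfind(".//abstract//p")]
    abstract = _collapse_ws(" ".join(part for part in abstract_parts if part))

    body = root.find(".//body")
    para_texts: list[str] = []
    if body is not None:
        para_texts = [_text_of(p) for p in body.iterfind(".//p")]

    def _meta_text(*paths: str) -> str:
        for path in paths:
            el = root.find(path)
            if el is not None:
                return _text_of(el)
        return ""

    authors = [
        _collapse_ws(" ".join(filter(None, (_text_of(n),))))
        for n in root.iterfind(".//contrib[@contrib-type='author']//name")
    ]
    meta = {
        "authors": [a for a in authors if a],
        "journal": _meta_text(".//journal-title"),
        "pub_date": _meta_text(".//pub-date/string-date"),
        "doi": _meta_text(".//article-id[@pub-id-type='doi']"),
    }

    if not doc_id:
        doc_id = _meta_text(".//article-id[@pub-id-type='pmc']", ".//article-id") or title
    doc = Document(doc_id=doc_id, title=title, abstract=abstract, meta=meta)
    doc.paragraphs = [
        Paragraph(doc.doc_id, i, t) for i, t in enumerate(t for t in para_texts if t)
    ]
    return doc


_TOKEN_RE = re.compile(r"[a-z]+")


def is_english(doc: Document, stopword_ratio_min: float = 0.15) -> bool:
    """Heuristic language filter over title + abstract.

    True iff the fraction of lowercased alphabetic tokens found in the
    built-in English stopword list is at least ``stopword_ratio_min``.
    Deterministic; depends only on title, abstract and the threshold.
    Documents with no alphabetic token are treated as non-English.
    """
    text = f"{doc.title} {doc.abstract}".lower()
    tokens = _TOKEN_RE.findall(text)
    if not tokens:
        return False
    hits = sum(1 for t in tokens if t in ENGLISH_STOPWORDS)
    return hits / len(tokens) >= stopword_ratio_min


def write_corpus(docs: Iterable[Document], path: str | Path) -> int:
    """Write documents as line-delimited JSON; returns the document count."""
    path = Path(path)
    n = 0
    with path.open("w", encoding="utf-8") as fh:
        for doc in docs:
            fh.write(json.dumps(doc.to_record(), sort_keys=True) + "\n")
            n += 1
    return n


def read_corpus(path: str | Path, format: str = "jsonl") -> list[Document]:
    """Read a corpus from JSONL or a directory of per-document XML files.

    Documents are returned in deterministic order (lexicographic by
    ``doc_id``).  Duplicate ids raise :class:`CorpusError`.
    """
    path = Path(path)
    docs: list[Document] = []
    if format == "jsonl":
        with path.open("r", encoding="utf-8") as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line:
                    continue
                try:
                    docs.append(Document.from_record(json.loads(line)))
                except (json.JSONDecodeError, KeyError) as exc:
                    raise CorpusError(f"{path}:{lineno}: bad corpus record: {exc}") from exc
    elif format == "xml_dir":
        for xml_path in sorted(path.glob("*.xml")):
            docs.append(parse_pmc_xml(xml_path.read_bytes(), doc_id=xml_path.stem))
    else:
        raise CorpusError(f"unknown corpus format: {format!r}")

    docs.sort(key=lambda d: d.doc_id)
    seen: dict[str, int] = {}
    for doc in docs:
        seen[doc.doc_id] = seen.get(doc.doc_id, 0) + 1
    dups = sorted(k for k, v in seen.items() if v > 1)
    if dups:
        raise CorpusError(f"duplicate doc_id(s) in corpus: {', '.join(dups)}")
    return docs


def paragraph_stream(
    docs: Sequence[Document], include_abstract: bool = False
) -> Iterator[Paragraph]:
    """Yield every paragraph of every document once, in (doc, index) order.

    With ``include_abstract`` the abstract is prepended as a pseudo-paragraph
    at index -1 (off by default: body text only).
    """
    for doc in docs:
        if include_abstract and doc.abstract:
            yield Paragraph(doc.doc_id, -1, doc.abstract)
        yield from doc.paragraphs
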