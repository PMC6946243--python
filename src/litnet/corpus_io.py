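"""Bibliographic corpus handling: parsing, sentence segmentation, persistence.

A :class:`Document` is one bibliographic record (id, title, abstract) plus an
ordered list of sentence intervals into its combined text.  Sentences are the
counting unit for gene-gene co-citation; whole documents are the counting unit
for gene-disease co-occurrence.  Segmentation is a fixed deterministic rule set
(terminal punctuation followed by whitespace and an uppercase letter or digit,
with an abbreviation guard list) so that every downstream count is reproducible.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from lxml import etree

__all__ = [
    "Document",
    "Corpus",
    "CorpusError",
    "CorpusParseError",
    "CorpusValidationError",
    "DEFAULT_ABBREVIATIONS",
    "segment_sentences",
    "parse_pubmed_xml",
    "parse_plaintext_corpus",
    "write_corpus",
]

#: Separator placed between title and abstract in the combined document text.
TITLE_SEP = "\n"

#: Lower-cased tokens (with trailing period) that never end a sentence.
DEFAULT_ABBREVIATIONS = frozenset(
    {
        "fig.", "figs.", "eq.", "eqs.", "ref.", "refs.", "al.", "e.g.", "i.e.",
        "vs.", "cf.", "ca.", "approx.", "no.", "nos.", "dr.", "st.", "resp.",
        "spp.", "sp.", "wk.", "mo.", "yr.",
    }
)


class CorpusError(ValueError):
    """Base class for corpus-level failures."""


class CorpusParseError(CorpusError):
    """Raised when an input file cannot be parsed."""


class CorpusValidationError(CorpusError):
    """Raised when parsed content violates a corpus invariant."""


@dataclass(frozen=True)
class Document:
    """One bibliographic record with optional sentence segmentation.

    ``sentences`` holds 0-based half-open character intervals into
    :attr:`text` (title, a separator newline, then abstract).  When the title
    is non-blank it occupies the first interval as a single sentence.
    """

    doc_id: str
    title: str
    abstract: str
    sentences: tuple[tuple[int, int], ...] = field(default=())

    @property
    def text(self) -> str:
        return self.title + TITLE_SEP + self.abstract

    @property
    def has_title_sentence(self) -> bool:
        return bool(self.title.strip())

    def sentence_text(self, index: int) -> str:
        a, b = self.sentences[index]
        return self.text[a:b]


@dataclass
class Corpus:
    """An ordered collection of documents with unique identifiers."""

    documents: list[Document]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for doc in self.documents:
            if doc.doc_id in seen:
                raise CorpusValidationError(f"duplicate doc_id {doc.doc_id!r}")
            seen.add(doc.doc_id)

    @property
    def size(self) -> int:
        return len(self.documents)

    def __len__(self) -> int:
        return len(self.documents)

    def __iter__(self) -> Iterator[Document]:
        return iter(self.documents)

    def __getitem__(self, i: int) -> Document:
        return self.documents[i]


def _trimmed(text: str, start: int, end: int) -> tuple[int, int] | None:
    """Shrink [start, end) to exclude flanking whitespace; None if blank."""
    while start < end and text[start].isspace():
        start += 1
    while end > start and text[end - 1].isspace():
        end -= 1
    if start == end:
        return None
    return (start, end)


_TERMINAL_RE = re.compile(r"[.!?]+")
_WORD_BEFORE_RE = re.compile(r"(\S+)$")


def _split_text(text: str, abbreviations: frozenset[str]) -> list[tuple[int, int]]:
    """Sentence spans (local coordinates) for a block of running text."""
    if not text.strip():
        return []
    spans: list[tuple[int, int]] = []
    start = 0
    for m in _TERMINAL_RE.finditer(text):
        end = m.end()
        if end >= len(text):
            break
        # boundary requires whitespace then an uppercase letter or digit
        j = end
        while j < len(text) and text[j].isspace():
            j += 1
        if j == end or j >= len(text):
            continue
        if not (text[j].isupper() or text[j].isdigit()):
            continue
        wm = _WORD_BEFORE_RE.search(text, 0, end)
        if wm and wm.group(1).lower() in abbreviations:
            continue
        span = _trimmed(text, start, end)
        if span:
            spans.append(span)
        start = j
    span = _trimmed(text, start, len(text))
    if span:
        spans.append(span)
    return spans


def segment_sentences(
    doc: Document, abbreviations: frozenset[str] = DEFAULT_ABBREVIATIONS
) -> Document:
    """Return a copy of ``doc`` with sentence intervals populated.

    The title (if non-blank) is always a single sentence; the abstract is
    split on terminal punctuation (. ! ?) followed by whitespace and an
    uppercase letter or digit, unless the preceding token is in the
    abbreviation guard list.  Idempotent: intervals depend only on the text.
    """
    spans: list[tuple[int, int]] = []
    title_span = _trimmed(doc.title, 0, len(doc.title))
    if title_span:
        spans.append(title_span)
    offset = len(doc.title) + len(TITLE_SEP)
    for a, b in _split_text(doc.abstract, abbreviations):
        spans.append((a + offset, b + offset))
    return replace(doc, sentences=tuple(spans))


def _collect_text(elem: etree._Element | None) -> str:
    if elem is None:
        return ""
    return "".join(elem.itertext()).strip()


def parse_pubmed_xml(path: str | Path, *, segment: bool = True) -> Corpus:
    """Parse a PubMed/MEDLINE article-set XML file into a :class:`Corpus`.

    One document per ``PubmedArticle`` element, in file order.  Articles
    without an abstract are retained with an empty abstract.  Multiple
    ``AbstractText`` sections are joined with single spaces.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(
            f"{path}: malformed XML at line {exc.lineno}, column {exc.offset}: {exc.msg}"
        ) from exc
    docs: list[Document] = []
    for art in tree.iter("PubmedArticle"):
        pmid = art.findtext(".//PMID")
        if pmid is None or not pmid.strip():
            raise CorpusValidationError(f"{path}: article without a PMID")
        title = _collect_text(art.find(".//ArticleTitle"))
        abstract = " ".join(
            t for t in (_collect_text(e) for e in art.iter("AbstractText")) if t
        )
        doc = Document(doc_id=pmid.strip(), title=title, abstract=abstract)
        docs.append(segment_sentences(doc) if segment else doc)
    return Corpus(docs)


_REQUIRED_KEYS = ("doc_id", "title", "abstract")


def parse_plaintext_corpus(path: str | Path, *, segment: bool = True) -> Corpus:
    """Parse a JSON Lines corpus (keys doc_id/title/abstract) into a Corpus."""
    path = Path(path)
    docs: list[Document] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                rec = json.loads(line)
            except json.JSONDecodeError as exc:
                raise CorpusParseError(f"{path}: line {lineno}: invalid JSON: {exc}") from exc
            for key in _REQUIRED_KEYS:
                if key not in rec:
                    raise CorpusValidationError(f"{path}: line {lineno}: missing key {key!r}")
            doc = Document(
                doc_id=str(rec["doc_id"]),
                title=str(rec["title"]),
                abstract=str(rec["abstract"]),
            )
            docs.append(segment_sentences(doc) if segment else doc)
    return Corpus(docs)


def write_corpus(corpus: Corpus, path: str | Path) -> Path:
    """Write a corpus as JSON Lines (with sentence intervals when present)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        for doc in corpus:
            rec = {
                "doc_id": doc.doc_id,
                "title": doc.title,
                "abstract": doc.abstract,
                "sentences": [list(s) for s in doc.sentences],
            }
            fh.write(json.dumps(rec, sort_keys=True) + "\n")
    return path
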