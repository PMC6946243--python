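"""Dictionary-based gene mention tagging and conjunction resolution.

Matching is deterministic: case-insensitive, token-boundary anchored, longest
match first, with hyphen/space equivalence so that ``IL-6``, ``IL6`` and
``il 6`` all normalize to the same lexicon key.  Aliases that collide across
genes after normalization are dropped at load time; an optional stop-list
removes aliases that collide with common English words.

Conjunction resolution expands coordinated elided forms -- ``IL-2, -4 and -6``
or ``MMP-2/9`` -- into individual mentions.  Expansions are re-validated
against the lexicon before emission, so the pattern set can afford to be
permissive.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .corpus_io import Corpus, Document

__all__ = [
    "LexiconEntry",
    "Lexicon",
    "LexiconError",
    "Mention",
    "TokenMatcher",
    "normalize_term",
    "load_lexicon",
    "tag_mentions",
    "resolve_conjunctions",
    "tag_corpus",
]

logger = logging.getLogger(__name__)

#: Characters allowed between tokens of a multi-token or hyphenated alias.
_JOINERS = frozenset(" -‐‑")

_NORM_RE = re.compile(r"[\s\-‐‑]+")
_TOKEN_RE = re.compile(r"[A-Za-z0-9]+")


class LexiconError(ValueError):
    """Raised for malformed or inconsistent lexicon input."""


def normalize_term(term: str) -> str:
    """Case-fold and strip spaces/hyphens: the canonical match key."""
    return _NORM_RE.sub("", term).casefold()


@dataclass(frozen=True)
class LexiconEntry:
    """One gene: stable identifier, canonical symbol, alias set."""

    gene_id: str
    symbol: str
    synonyms: tuple[str, ...] = ()

    def aliases(self) -> tuple[str, ...]:
        return (self.symbol,) + self.synonyms


@dataclass(frozen=True)
class Mention:
    """A normalized gene mention located in a document sentence.

    ``start``/``end`` are 0-based half-open offsets into the document's
    combined text and always fall inside the interval of ``sentence_index``.
    """

    doc_id: str
    sentence_index: int
    start: int
    end: int
    surface: str
    gene_id: str


@dataclass(frozen=True)
class _Match:
    start: int
    end: int
    surface: str
    label: str


class TokenMatcher:
    """Greedy longest-match phrase matcher over alphanumeric tokens.

    Phrases are indexed by their normalized form; candidate spans are token
    runs whose inter-token gaps consist only of spaces/hyphens (at most 3
    characters), which yields the hyphen/space equivalence classes.
    """

    def __init__(self) -> None:
        self._index: dict[str, str] = {}
        self.max_tokens = 0

    def __len__(self) -> int:
        return len(self._index)

    def __contains__(self, key: str) -> bool:
        return key in self._index

    def add(self, phrase: str, label: str) -> None:
        key = normalize_term(phrase)
        if not key:
            raise LexiconError(f"phrase {phrase!r} normalizes to nothing")
        self._index[key] = label
        self.max_tokens = max(self.max_tokens, len(_TOKEN_RE.findall(phrase)))

    def remove(self, phrase: str) -> None:
        self._index.pop(normalize_term(phrase), None)

    def lookup(self, key: str) -> str | None:
        return self._index.get(key)

    def find(self, text: str) -> list[_Match]:
        tokens = list(_TOKEN_RE.finditer(text))
        out: list[_Match] = []
        i = 0
        n = len(tokens)
        while i < n:
            matched = False
            for L in range(min(self.max_tokens, n - i), 0, -1):
                a = tokens[i].start()
                b = tokens[i + L - 1].end()
                if L > 1:
                    ok = True
                    for j in range(i, i + L - 1):
                        gap = text[tokens[j].end() : tokens[j + 1].start()]
                        if len(gap) > 3 or not set(gap) <= _JOINERS:
                            ok = False
                            break
                    if not ok:
                        continue
                surface = text[a:b]
                label = self._index.get(normalize_term(surface))
                if label is not None:
                    out.append(_Match(a, b, surface, label))
                    i += L
                    matched = True
                    break
            if not matched:
                i += 1
        return out


class Lexicon:
    """Gene lexicon with a collision-free normalized alias index."""

    def __init__(
        self, entries: Iterable[LexiconEntry], stop_aliases: Iterable[str] = ()
    ) -> None:
        self.entries: dict[str, LexiconEntry] = {}
        for entry in entries:
            if entry.gene_id in self.entries:
                raise LexiconError(f"duplicate gene_id {entry.gene_id!r}")
            if not entry.symbol:
                raise LexiconError(f"gene {entry.gene_id!r} has an empty symbol")
            self.entries[entry.gene_id] = entry

        stop = {normalize_term(s) for s in stop_aliases}
        alias_map: dict[str, set[str]] = {}
        alias_surface: dict[str, str] = {}
        for entry in self.entries.values():
            for alias in entry.aliases():
                key = normalize_term(alias)
                if not key or key in stop:
                    continue
                alias_map.setdefault(key, set()).add(entry.gene_id)
                alias_surface.setdefault(key, alias)

        self.matcher = TokenMatcher()
        dropped: list[str] = []
        for key, gene_ids in alias_map.items():
            if len(gene_ids) > 1:
                dropped.append(alias_surface[key])
                continue
            self.matcher.add(alias_surface[key], next(iter(gene_ids)))
        self.dropped_aliases: tuple[str, ...] = tuple(sorted(dropped))
        if dropped:
            logger.warning(
                "dropped %d ambiguous aliases mapping to multiple genes", len(dropped)
            )

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.entries

    def symbol_of(self, gene_id: str) -> str:
        return self.entries[gene_id].symbol

    def lookup_alias(self, term: str) -> str | None:
        """gene_id for a surface term (normalized), or None."""
        return self.matcher.lookup(normalize_term(term))

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(self.entries)


def load_lexicon(
    path: str | Path, stoplist_path: str | Path | None = None
) -> Lexicon:
    """Load a TSV lexicon (gene_id, symbol, pipe-separated synonyms).

    Lines starting with ``#`` are comments.  The synonyms column may be empty
    or absent.  Ambiguous aliases (mapping to more than one gene after
    normalization) are dropped from the match index and logged.
    """
    path = Path(path)
    entries: list[LexiconEntry] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise LexiconError(f"{path}: line {lineno}: expected >=2 tab-separated fields")
            gene_id, symbol = parts[0].strip(), parts[1].strip()
            synonyms: tuple[str, ...] = ()
            if len(parts) >= 3 and parts[2].strip():
                synonyms = tuple(s.strip() for s in parts[2].split("|") if s.strip())
            entries.append(LexiconEntry(gene_id, symbol, synonyms))
    stop: list[str] = []
    if stoplist_path is not None:
        with Path(stoplist_path).open(encoding="utf-8") as fh:
            stop = [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]
    return Lexicon(entries, stop_aliases=stop)


def write_lexicon(entries: Sequence[LexiconEntry], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#gene_id\tsymbol\tsynonyms\n")
        for e in entries:
            fh.write(f"{e.gene_id}\t{e.symbol}\t{'|'.join(e.synonyms)}\n")
    return path


def tag_mentions(
    doc: Document, lexicon: Lexicon, *, include_title: bool = True
) -> list[Mention]:
    """Tag gene mentions in every sentence of a segmented document.

    Longest-match, non-overlapping, token-boundary anchored; each match is
    normalized to its lexicon gene_id.  Set ``include_title=False`` to skip
    the title sentence.
    """
    if (doc.title.strip() or doc.abstract.strip()) and not doc.sentences:
        raise ValueError(f"document {doc.doc_id!r} is not segmented")
    mentions: list[Mention] = []
    text = doc.text
    for s_idx, (a, b) in enumerate(doc.sentences):
        if not include_title and s_idx == 0 and doc.has_title_sentence:
            continue
        for m in lexicon.matcher.find(text[a:b]):
            mentions.append(
                Mention(doc.doc_id, s_idx, a + m.start, a + m.end, m.surface, m.label)
            )
    return mentions


# Conjunction patterns.  Head: a letter stem directly followed (optionally via
# one hyphen/space) by a numeric or single-letter designator.  Tail: one or
# more coordinated elided designators introduced by ',', '/', 'and' or 'or',
# optionally preceded by a hyphen or slash ("IL-2, -4 and -6"; "MMP-2/9").
_HEAD_RE = re.compile(r"\b([A-Za-z]{2,})[\-‐ ]?(\d+|[A-Za-z])(?![A-Za-z0-9])")
_TAIL_RE = re.compile(
    r"\s*(?:/|,|(?:,\s*)?\b(?:and|or)\b)\s*[\-‐/]?\s*(\d+|[A-Za-z])(?![A-Za-z0-9])"
)


def resolve_conjunctions(
    sentence_text: str,
    mentions: Sequence[Mention],
    lexicon: Lexicon,
    *,
    doc_id: str = "",
    sentence_index: int = 0,
    offset: int = 0,
) -> list[Mention]:
    """Expand coordinated elided gene mentions within one sentence.

    ``mentions`` are the already-tagged mentions of this sentence (spans in
    document coordinates when ``offset`` is the sentence start).  Candidate
    expansions (stem + designator) are validated against the lexicon; spans of
    expanded mentions point at the eliding fragment.  Returns the input
    mentions plus any new expansions, sorted by position.
    """
    if mentions:
        doc_id = mentions[0].doc_id
        sentence_index = mentions[0].sentence_index
    out = list(mentions)

    def covered(gene_id: str, start: int, end: int) -> bool:
        return any(
            m.gene_id == gene_id and m.start < end and m.end > start for m in out
        )

    for head in _HEAD_RE.finditer(sentence_text):
        pos = head.end()
        tails: list[tuple[int, int]] = []
        while True:
            tm = _TAIL_RE.match(sentence_text, pos)
            if tm is None:
                break
            tails.append((tm.start(1), tm.end(1)))
            pos = tm.end()
        if not tails:
            continue
        stem = head.group(1)
        candidates = [(head.start(), head.end())] + tails
        designators = [head.group(2)] + [sentence_text[a:b] for a, b in tails]
        for (a, b), designator in zip(candidates, designators):
            gene_id = lexicon.lookup_alias(stem + designator)
            if gene_id is None:
                continue
            # include the immediately-preceding hyphen of an elided fragment
            if a > 0 and sentence_text[a - 1] in "-‐":
                a -= 1
            g_start, g_end = a + offset, b + offset
            if covered(gene_id, g_start, g_end):
                continue
            out.append(
                Mention(
                    doc_id,
                    sentence_index,
                    g_start,
                    g_end,
                    sentence_text[a:b],
                    gene_id,
                )
            )
    out.sort(key=lambda m: (m.start, m.end, m.gene_id))
    return out


def tag_corpus(
    corpus: Corpus,
    lexicon: Lexicon,
    *,
    include_title: bool = True,
    resolve: bool = True,
) -> list[Mention]:
    """Tag (and optionally conjunction-resolve) every document of a corpus."""
    all_mentions: list[Mention] = []
    for doc in corpus:
        tagged = tag_mentions(doc, lexicon, include_title=include_title)
        if not resolve:
            all_mentions.extend(tagged)
            continue
        by_sentence: dict[int, list[Mention]] = {}
        for m in tagged:
            by_sentence.setdefault(m.sentence_index, []).append(m)
        for s_idx, (a, b) in enumerate(doc.sentences):
            if not include_title and s_idx == 0 and doc.has_title_sentence:
                continue
            sent_mentions = by_sentence.get(s_idx, [])
            all_mentions.extend(
                resolve_conjunctions(
                    doc.text[a:b],
                    sent_mentions,
                    lexicon,
                    doc_id=doc.doc_id,
                    sentence_index=s_idx,
                    offset=a,
                )
            )
    return all_mentions


def write_mentions(mentions: Sequence[Mention], path: str | Path) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("doc_id\tsentence_index\tstart\tend\tsurface\tgene_id\n")
        for m in mentions:
            fh.write(
                f"{m.doc_id}\t{m.sentence_index}\t{m.start}\t{m.end}\t{m.surface}\t{m.gene_id}\n"
            )
    return path
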