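"""Gene-disease co-occurrence scoring with the hypergeometric tail statistic.

For a corpus of N documents in which n mention the disease and m mention a
given gene, with k mentioning both, the association statistic is the upper
tail of the hypergeometric distribution

    P(X >= k) = sum_{i=k}^{min(m,n)} C(m,i) C(N-m, n-i) / C(N,n),

the probability of at least k joint documents if the gene's m documents were
placed uniformly at random among the N.  Counting is document-level and
binary: a document counts once for a gene no matter how many mentions it
contains.  Genes with P below a significance threshold (0.05 by default, raw
-- no multiplicity correction -- with Benjamini-Hochberg available as an
opt-in mode) form the disease-associated gene set.

The tail is evaluated in log space with a pmf ratio recurrence, which is
overflow-free for corpora up to ~1e7 documents and agrees with exact
big-integer enumeration to well under 1e-12 for small N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .corpus_io import Corpus
from .ner import Lexicon, Mention, TokenMatcher

__all__ = [
    "CooccurrenceCounts",
    "AssociationResult",
    "hypergeom_tail",
    "disease_documents",
    "count_gene_disease",
    "score_all_genes",
    "rank_by_frequency",
    "write_results_tsv",
]


@dataclass(frozen=True)
class CooccurrenceCounts:
    """Document counts for one gene against the disease query.

    N: corpus size; n: documents mentioning the disease; m: documents
    mentioning the gene; k: documents mentioning both.
    """

    N: int
    n: int
    m: int
    k: int

    def __post_init__(self) -> None:
        if not all(isinstance(v, int) for v in (self.N, self.n, self.m, self.k)):
            raise ValueError("counts must be integers")
        if self.N < 1:
            raise ValueError("corpus size N must be >= 1")
        if not (0 <= self.m <= self.N and 0 <= self.n <= self.N):
            raise ValueError(f"need 0 <= m,n <= N, got m={self.m} n={self.n} N={self.N}")
        if not (0 <= self.k <= min(self.m, self.n)):
            raise ValueError(f"need 0 <= k <= min(m,n), got k={self.k} m={self.m} n={self.n}")


@dataclass(frozen=True)
class AssociationResult:
    """Scored association between one gene and the disease."""

    gene_id: str
    counts: CooccurrenceCounts
    p_value: float
    significant: bool
    q_value: float | None = None


def _log_comb(a: int, b: int) -> float:
    return math.lgamma(a + 1) - math.lgamma(b + 1) - math.lgamma(a - b + 1)


def hypergeom_tail(k: int, m: int, n: int, N: int, *, strict: bool = False) -> float:
    """Upper-tail hypergeometric probability P(X >= k) (P(X > k) if strict).

    X counts the overlap of an m-subset and an n-subset drawn from N items.
    Symmetric in m and n.  Raises ValueError when the count invariants are
    violated (k outside [0, min(m, n)] or m, n outside [0, N]).
    """
    for name, v in (("k", k), ("m", m), ("n", n), ("N", N)):
        if not isinstance(v, (int,)):
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if N < 1 or not (0 <= m <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= m,n <= N and N >= 1; got m={m} n={n} N={N}")
    hi = min(m, n)
    if not (0 <= k <= hi):
        raise ValueError(f"need 0 <= k <= min(m,n); got k={k} min={hi}")
    if strict:
        k = k + 1
        if k > hi:
            return 0.0
    lo = max(k, m + n - N)  # below lo the pmf is zero; k below it means P = 1
    if k <= max(0, m + n - N) and k <= 0:
        return 1.0
    if lo > hi:
        return 0.0
    # log pmf at the lowest contributing overlap, then ratio recurrence
    lp = _log_comb(m, lo) + _log_comb(N - m, n - lo) - _log_comb(N, n)
    logs = [lp]
    for i in range(lo, hi):
        lp += math.log((m - i) * (n - i)) - math.log((i + 1) * (N - m - n + i + 1))
        logs.append(lp)
    mx = max(logs)
    total = 0.0
    for l in logs:
        total += math.exp(l - mx)
    p = math.exp(mx + math.log(total))
    return min(1.0, max(0.0, p))


def disease_documents(
    corpus: Corpus,
    disease_terms: Iterable[str],
    *,
    include_title: bool = True,
) -> set[str]:
    """doc_ids whose text mentions any disease term (same matcher rules as genes)."""
    matcher = TokenMatcher()
    n_terms = 0
    for term in disease_terms:
        matcher.add(term, "disease")
        n_terms += 1
    if n_terms == 0:
        raise ValueError("disease_terms must be non-empty")
    hits: set[str] = set()
    for doc in corpus:
        text = doc.text
        for s_idx, (a, b) in enumerate(doc.sentences):
            if not include_title and s_idx == 0 and doc.has_title_sentence:
                continue
            if matcher.find(text[a:b]):
                hits.add(doc.doc_id)
                break
    return hits


def count_gene_disease(
    corpus: Corpus,
    mentions: Sequence[Mention],
    disease_terms: Iterable[str],
    *,
    genes: Iterable[str] | None = None,
    include_title: bool = True,
) -> dict[str, CooccurrenceCounts]:
    """Document-level binary co-occurrence counts for each gene vs the disease.

    ``genes`` optionally fixes the gene universe (absent genes get m = k = 0);
    by default it is the set of genes with at least one mention.
    """
    if corpus.size == 0:
        raise ValueError("cannot count over an empty corpus")
    N = corpus.size
    disease_docs = disease_documents(corpus, disease_terms, include_title=include_title)
    n = len(disease_docs)
    gene_docs: dict[str, set[str]] = {}
    for m in mentions:
        gene_docs.setdefault(m.gene_id, set()).add(m.doc_id)
    universe = list(genes) if genes is not None else sorted(gene_docs)
    counts: dict[str, CooccurrenceCounts] = {}
    for gene_id in universe:
        docs = gene_docs.get(gene_id, set())
        counts[gene_id] = CooccurrenceCounts(
            N=N, n=n, m=len(docs), k=len(docs & disease_docs)
        )
    return counts


def _bh_significant(pvals: Sequence[float], alpha: float) -> list[bool]:
    """Benjamini-Hochberg step-up significance flags at level alpha."""
    M = len(pvals)
    order = sorted(range(M), key=lambda i: pvals[i])
    cutoff = -1.0
    for rank, idx in enumerate(order, start=1):
        if pvals[idx] <= rank / M * alpha:
            cutoff = pvals[idx]
    return [p <= cutoff for p in pvals]


def score_all_genes(
    counts_map: Mapping[str, CooccurrenceCounts],
    alpha: float = 0.05,
    *,
    correction: str | None = None,
    strict_tail: bool = False,
) -> list[AssociationResult]:
    """Hypergeometric association score for every gene with at least one mention.

    Results are sorted by ascending p-value, ties broken by descending k then
    lexicographic gene_id.  Significance uses raw p < alpha by default;
    ``correction="bh"`` switches to Benjamini-Hochberg.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if correction not in (None, "bh"):
        raise ValueError(f"unknown correction {correction!r}")
    items = [(g, c) for g, c in counts_map.items() if c.m >= 1]
    pvals = [
        hypergeom_tail(c.k, c.m, c.n, c.N, strict=strict_tail) for _, c in items
    ]
    if correction == "bh" and items:
        flags = _bh_significant(pvals, alpha)
    else:
        flags = [p < alpha for p in pvals]
    results = [
        AssociationResult(gene_id=g, counts=c, p_value=p, significant=sig)
        for (g, c), p, sig in zip(items, pvals, flags)
    ]
    results.sort(key=lambda r: (r.p_value, -r.counts.k, r.gene_id))
    return results


def rank_by_frequency(
    counts_map: Mapping[str, CooccurrenceCounts], top: int
) -> list[str]:
    """Genes ordered by descending co-citation frequency with the disease (k)."""
    if top < 1:
        raise ValueError(f"top must be >= 1, got {top}")
    ranked = sorted(counts_map, key=lambda g: (-counts_map[g].k, g))
    return ranked[:top]


def write_results_tsv(
    results: Sequence[AssociationResult],
    path: str | Path,
    lexicon: Lexicon | None = None,
) -> Path:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("gene_id\tsymbol\tk\tm\tn\tN\tp_value\tsignificant\n")
        for r in results:
            symbol = lexicon.symbol_of(r.gene_id) if lexicon else r.gene_id
            c = r.counts
            fh.write(
                f"{r.gene_id}\t{symbol}\t{c.k}\t{c.m}\t{c.n}\t{c.N}\t"
                f"{r.p_value!r}\t{int(r.significant)}\n"
            )
    return path
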