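"""Over-representation analysis of a gene set against GO and pathway collections.

Each annotation term is tested with the same hypergeometric upper tail used
for gene-disease scoring: with a background universe of B genes, a term
covering t of them and a query of q genes sharing o with the term,

    p = P(X >= o),  X ~ Hypergeometric(B, t, q),

which equals the one-sided Fisher exact test on the 2x2 overlap table.  The
background defaults to the annotated genes (the DAVID convention) so that
unannotatable genes do not deflate p-values; term gene sets are intersected
with the background before testing.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .cooccurrence import hypergeom_tail

__all__ = [
    "NAMESPACES",
    "TermAnnotation",
    "EnrichmentResult",
    "AnnotationError",
    "load_gmt",
    "load_gaf",
    "annotated_background",
    "enrich",
    "summarize_by_namespace",
    "write_enrichment_tsv",
]

NAMESPACES = ("BP", "CC", "MF", "PATHWAY")

#: GAF aspect column -> GO namespace.
GAF_ASPECT_MAP = {"P": "BP", "F": "MF", "C": "CC"}


class AnnotationError(ValueError):
    """Raised for malformed annotation input."""


@dataclass(frozen=True)
class TermAnnotation:
    """One gene-set term (GO term or pathway) with its member genes."""

    term_id: str
    term_name: str
    namespace: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES:
            raise AnnotationError(f"unknown namespace {self.namespace!r}")
        if not self.genes:
            raise AnnotationError(f"term {self.term_id!r} has no genes")


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric over-representation result for one term."""

    term_id: str
    term_name: str
    namespace: str
    overlap: int
    term_size: int
    query_size: int
    background_size: int
    p_value: float
    significant: bool


def load_gmt(path: str | Path, namespace: str) -> list[TermAnnotation]:
    """Read a GMT gene-set file; every line becomes one term in ``namespace``."""
    if namespace not in NAMESPACES:
        raise AnnotationError(f"unknown namespace {namespace!r}")
    path = Path(path)
    terms: list[TermAnnotation] = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise AnnotationError(
                    f"{path}: line {lineno}: GMT lines need term, description and >=1 gene"
                )
            genes = frozenset(g.strip() for g in parts[2:] if g.strip())
            if not genes:
                raise AnnotationError(f"{path}: line {lineno}: empty gene list")
            terms.append(TermAnnotation(parts[0].strip(), parts[1].strip(), namespace, genes))
    return terms


def load_gaf(
    path: str | Path, namespace_map: Mapping[str, str] = GAF_ASPECT_MAP
) -> list[TermAnnotation]:
    """Read GAF 2.x GO annotations, grouped by term; NOT-qualified rows skipped.

    Columns used: 2 (gene id), 4 (qualifier), 5 (GO id), 9 (aspect P/F/C).
    """
    path = Path(path)
    grouped: dict[str, tuple[str, set[str]]] = {}
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("!"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise AnnotationError(f"{path}: line {lineno}: expected >=9 GAF columns")
            gene_id, qualifier, go_id, aspect = cols[1], cols[3], cols[4], cols[8]
            if "NOT" in qualifier.split("|"):
                continue
            if aspect not in namespace_map:
                raise AnnotationError(f"{path}: line {lineno}: unknown aspect {aspect!r}")
            ns = namespace_map[aspect]
            key = go_id
            if key not in grouped:
                grouped[key] = (ns, set())
            elif grouped[key][0] != ns:
                raise AnnotationError(f"{path}: term {go_id} appears under two aspects")
            grouped[key][1].add(gene_id)
    return [
        TermAnnotation(term_id, term_id, ns, frozenset(genes))
        for term_id, (ns, genes) in grouped.items()
        if genes
    ]


def annotated_background(annotations: Iterable[TermAnnotation]) -> frozenset[str]:
    """All genes appearing in at least one annotation term."""
    bg: set[str] = set()
    for t in annotations:
        bg |= t.genes
    return frozenset(bg)


def enrich(
    query: Iterable[str],
    background: Iterable[str],
    annotations: Sequence[TermAnnotation],
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Hypergeometric over-representation of ``query`` in each annotation term.

    Requires query to be a subset of background.  Term gene sets are
    intersected with the background; terms with zero overlap are reported
    with p = 1.  Results are sorted by ascending p, then term_id.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    query_set = frozenset(query)
    bg = frozenset(background)
    stray = query_set - bg
    if stray:
        raise ValueError(
            "query genes missing from background: " + ", ".join(sorted(stray))
        )
    B, q = len(bg), len(query_set)
    if B == 0:
        raise ValueError("background is empty")
    results: list[EnrichmentResult] = []
    for term in annotations:
        term_genes = term.genes & bg
        t = len(term_genes)
        if t == 0:
            continue
        o = len(term_genes & query_set)
        p = 1.0 if o == 0 else hypergeom_tail(o, t, q, B)
        results.append(
            EnrichmentResult(
                term_id=term.term_id,
                term_name=term.term_name,
                namespace=term.namespace,
                overlap=o,
                term_size=t,
                query_size=q,
                background_size=B,
                p_value=p,
                significant=p < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term_id))
    return results


def summarize_by_namespace(
    results: Sequence[EnrichmentResult],
) -> dict[str, list[EnrichmentResult]]:
    """Significant terms grouped by namespace (BP/CC/MF/PATHWAY).

    Every namespace key is present, possibly with an empty list; this is the
    data backbone of the namespace histogram report.
    """
    groups: dict[str, list[EnrichmentResult]] = {ns: [] for ns in NAMESPACES}
    for r in results:
        if r.significant:
            groups[r.namespace].append(r)
    return groups


def write_enrichment_tsv(
    results: Sequence[EnrichmentResult], path: str | Path
) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        [
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "namespace": r.namespace,
                "overlap": r.overlap,
                "term_size": r.term_size,
                "query_size": r.query_size,
                "background_size": r.background_size,
                "p_value": repr(r.p_value),
                "significant": int(r.significant),
            }
            for r in results
        ],
        columns=[
            "term_id", "term_name", "namespace", "overlap", "term_size",
            "query_size", "background_size", "p_value", "significant",
        ],
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")
    return path
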