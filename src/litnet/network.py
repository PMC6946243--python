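"""Multi-evidence gene network: curated relations plus sentence co-citation.

Edges come from three evidence channels -- KEGG-style pathway relations
(ECrel/PPrel/GErel, read from KGML), tabulated protein-protein interactions,
and sentence-level gene co-citation scored with the hypergeometric tail --
and are merged into one undirected graph, deduplicated by gene pair with
evidence provenance retained.  The merged network supports degree-histogram
topology analysis, power-law exponent fitting (log-log least squares by
default, discrete MLE as an alternative), and hub extraction by degree.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
from lxml import etree

from .cooccurrence import hypergeom_tail
from .corpus_io import Corpus, CorpusParseError
from .ner import Mention

__all__ = [
    "RELATION_TYPES",
    "Evidence",
    "RelationEdge",
    "relation_edge",
    "GeneNetwork",
    "NetworkError",
    "PowerLawFit",
    "HubSet",
    "parse_kgml",
    "load_ppi_table",
    "cocitation_edges",
    "merge_network",
    "degree_histogram",
    "fit_power_law",
    "identify_hubs",
    "export_network",
    "import_graphml",
]

RELATION_TYPES = ("ECrel", "PPrel", "GErel", "cocitation")


class NetworkError(ValueError):
    """Raised for invalid network operations or inputs."""


@dataclass(frozen=True)
class Evidence:
    """Provenance of one edge observation: source tag, optional detail and p."""

    source: str
    detail: str = ""
    p_value: float | None = None


@dataclass(frozen=True)
class RelationEdge:
    """One undirected typed edge between two genes (canonical pair order)."""

    gene_a: str
    gene_b: str
    relation_type: str
    evidence: tuple[Evidence, ...] = ()

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise NetworkError(f"self-loop on {self.gene_a!r}")
        if self.gene_a > self.gene_b:
            raise NetworkError("edge pair not in canonical order; use relation_edge()")
        if self.relation_type not in RELATION_TYPES:
            raise NetworkError(f"unknown relation type {self.relation_type!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


def relation_edge(
    a: str,
    b: str,
    relation_type: str,
    evidence: Iterable[Evidence] = (),
) -> RelationEdge:
    """Build a RelationEdge with the pair in canonical (sorted) order."""
    if a > b:
        a, b = b, a
    return RelationEdge(a, b, relation_type, tuple(evidence))


class GeneNetwork:
    """Merged undirected gene graph with typed, evidence-bearing edges.

    Nodes exist only as edge endpoints (no isolated nodes are retained), so
    the handshake identity sum(degree) == 2 * n_edges always holds.
    """

    def __init__(self, graph: nx.Graph | None = None) -> None:
        self.graph = graph if graph is not None else nx.Graph()

    @property
    def nodes(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def edges(self) -> list[RelationEdge]:
        out: list[RelationEdge] = []
        for a, b, data in sorted(self.graph.edges(data=True)):
            for rel_type in sorted(data["types"]):
                out.append(RelationEdge(a, b, rel_type, tuple(data["evidence"])))
        return out

    def edge_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted(e)) for e in self.graph.edges()}

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneNetwork):
            return NotImplemented
        if self.nodes != other.nodes or self.edge_pairs() != other.edge_pairs():
            return False
        for a, b, data in self.graph.edges(data=True):
            odata = other.graph.edges[a, b]
            if set(data["types"]) != set(odata["types"]):
                return False
            if set(data["evidence"]) != set(odata["evidence"]):
                return False
        return True


def _gene_ids_from_kgml_name(name: str) -> list[str]:
    ids = []
    for token in name.split():
        ids.append(token.split(":", 1)[1] if ":" in token else token)
    return ids


def parse_kgml(path: str | Path) -> list[RelationEdge]:
    """Parse a KGML pathway file into typed relation edges.

    Only relations of type ECrel/PPrel/GErel between two gene entries are
    kept; relations touching compounds, maps or groups are skipped.  KGML
    entry names may list several genes ("hsa:1234 hsa:5678"); all pairs
    across the two entries are emitted.  Duplicate pairs (same type) are
    deduplicated; relation subtype names are kept as evidence detail.
    """
    path = Path(path)
    try:
        tree = etree.parse(str(path))
    except etree.XMLSyntaxError as exc:
        raise CorpusParseError(
            f"{path}: malformed XML at line {exc.lineno}, column {exc.offset}: {exc.msg}"
        ) from exc
    entries: dict[str, tuple[str, list[str]]] = {}
    for entry in tree.iter("entry"):
        entries[entry.get("id")] = (
            entry.get("type", ""),
            _gene_ids_from_kgml_name(entry.get("name", "")),
        )
    seen: dict[tuple[str, str, str], RelationEdge] = {}
    for rel in tree.iter("relation"):
        rel_type = rel.get("type")
        if rel_type not in ("ECrel", "PPrel", "GErel"):
            continue
        e1 = entries.get(rel.get("entry1"))
        e2 = entries.get(rel.get("entry2"))
        if e1 is None or e2 is None or e1[0] != "gene" or e2[0] != "gene":
            continue
        subtypes = ",".join(
            sorted(st.get("name", "") for st in rel.iter("subtype") if st.get("name"))
        )
        for a in e1[1]:
            for b in e2[1]:
                if a == b:
                    continue
                edge = relation_edge(
                    a, b, rel_type,
                    [Evidence(source=f"kgml:{path.name}", detail=subtypes)],
                )
                seen.setdefault((edge.gene_a, edge.gene_b, rel_type), edge)
    return list(seen.values())


def load_ppi_table(
    path: str | Path, valid_genes: Iterable[str] | None = None
) -> list[RelationEdge]:
    """Read a two-column TSV of interacting gene pairs as PPrel edges.

    Rows referencing a gene outside ``valid_genes`` (when given) are skipped,
    as are self-loops; (A,B) and (B,A) collapse to one canonical edge.
    """
    path = Path(path)
    valid = set(valid_genes) if valid_genes is not None else None
    seen: dict[tuple[str, str], RelationEdge] = {}
    n_skipped = 0
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise NetworkError(f"{path}: line {lineno}: expected two columns")
            a, b = parts[0].strip(), parts[1].strip()
            if a == b:
                continue
            if valid is not None and (a not in valid or b not in valid):
                n_skipped += 1
                continue
            edge = relation_edge(a, b, "PPrel", [Evidence(source="ppi-table")])
            seen.setdefault(edge.pair, edge)
    if n_skipped:
        import logging

        logging.getLogger(__name__).warning(
            "%s: skipped %d rows with genes outside the lexicon", path, n_skipped
        )
    return list(seen.values())


def cocitation_edges(
    corpus: Corpus,
    mentions: Sequence[Mention],
    alpha: float = 0.05,
    *,
    min_support: int = 2,
    strict_tail: bool = False,
) -> list[RelationEdge]:
    """Sentence-level gene-gene co-citation edges under the hypergeometric test.

    Counting is at sentence granularity: with N' total sentences in the
    corpus, m' and n' sentences mentioning each gene and k' mentioning both,
    a pair becomes a ``cocitation`` edge when P(X >= k') < alpha and
    k' >= min_support (default 2, suppressing single-sentence coincidences).
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    if min_support < 1:
        raise ValueError(f"min_support must be >= 1, got {min_support}")
    total_sentences = sum(len(doc.sentences) for doc in corpus)
    if total_sentences == 0:
        return []
    gene_sentences: dict[str, set[tuple[str, int]]] = {}
    sentence_genes: dict[tuple[str, int], set[str]] = {}
    for m in mentions:
        key = (m.doc_id, m.sentence_index)
        gene_sentences.setdefault(m.gene_id, set()).add(key)
        sentence_genes.setdefault(key, set()).add(m.gene_id)
    pair_counts: Counter[tuple[str, str]] = Counter()
    for genes in sentence_genes.values():
        if len(genes) < 2:
            continue
        ordered = sorted(genes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pair_counts[(a, b)] += 1
    edges: list[RelationEdge] = []
    for (a, b), k in sorted(pair_counts.items()):
        if k < min_support:
            continue
        p = hypergeom_tail(
            k,
            len(gene_sentences[a]),
            len(gene_sentences[b]),
            total_sentences,
            strict=strict_tail,
        )
        if p < alpha:
            edges.append(
                relation_edge(
                    a, b, "cocitation",
                    [Evidence(source="cocitation", detail=f"k={k}", p_value=p)],
                )
            )
    return edges


def merge_network(
    *edge_lists: Iterable[RelationEdge],
    restrict_to: Iterable[str] | None = None,
    restrict_mode: str = "both",
) -> GeneNetwork:
    """Undirected union of edge lists into one deduplicated gene network.

    The same gene pair contributed by several sources becomes one edge whose
    evidence records are merged and whose type set is the union.  With
    ``restrict_to``, edges are kept when both endpoints (mode "both") or at
    least one endpoint (mode "any") belong to the supplied gene set.
    Commutative and idempotent in its inputs.
    """
    if restrict_mode not in ("both", "any"):
        raise NetworkError(f"unknown restrict_mode {restrict_mode!r}")
    keep = set(restrict_to) if restrict_to is not None else None
    graph = nx.Graph()
    for edge_list in edge_lists:
        for edge in edge_list:
            a, b = edge.pair
            if keep is not None:
                inside = (a in keep) + (b in keep)
                if restrict_mode == "both" and inside < 2:
                    continue
                if restrict_mode == "any" and inside < 1:
                    continue
            if graph.has_edge(a, b):
                data = graph.edges[a, b]
                data["types"] = tuple(sorted(set(data["types"]) | {edge.relation_type}))
                merged = list(data["evidence"])
                for ev in edge.evidence:
                    if ev not in merged:
                        merged.append(ev)
                data["evidence"] = tuple(merged)
            else:
                graph.add_edge(
                    a, b, types=(edge.relation_type,), evidence=tuple(edge.evidence)
                )
    return GeneNetwork(graph)


def degree_histogram(network: GeneNetwork) -> dict[int, int]:
    """Exact integer histogram degree -> node count; counts sum to n_nodes."""
    if network.n_nodes == 0:
        raise NetworkError("cannot compute a degree histogram of an empty network")
    return dict(sorted(Counter(d for _, d in network.graph.degree()).items()))


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted degree-distribution exponent gamma for c(d) ~ d^-gamma.

    ``goodness`` is the R^2 of the log-log regression for the least-squares
    method, or the KS distance between the empirical tail and the fitted law
    for the MLE method (smaller is better there).
    """

    exponent: float
    method: str
    d_min: int
    goodness: float
    n_tail: int

    @property
    def is_power_law(self) -> bool:
        """Heuristic plausibility flag: a non-positive exponent is degenerate."""
        return self.exponent > 0.0


def fit_power_law(
    histogram: Mapping[int, int], *, method: str = "ls", d_min: int | str = 1
) -> PowerLawFit:
    """Fit the degree-distribution power-law exponent from a degree histogram.

    method "ls": least squares on (log d, log count) over degrees >= d_min
    with nonzero counts; gamma = -slope, goodness = R^2.  method "mle":
    discrete maximum likelihood gamma = 1 + n * (sum ln(d_i/(d_min - 1/2)))^-1
    with a KS goodness statistic; ``d_min="auto"`` selects the tail cutoff
    that minimizes the KS distance (the standard remedy for distributions
    that follow a power law only in their tail).  Requires >= 3 distinct
    supported degrees.
    """
    if method not in ("ls", "mle"):
        raise NetworkError(f"unknown fit method {method!r}")
    if d_min == "auto":
        if method != "mle":
            raise NetworkError('d_min="auto" is only available with method="mle"')
        best: PowerLawFit | None = None
        for candidate in sorted(d for d, c in histogram.items() if c > 0):
            try:
                fit = fit_power_law(histogram, method="mle", d_min=candidate)
            except NetworkError:
                break
            if best is None or fit.goodness < best.goodness:
                best = fit
        if best is None:
            raise NetworkError("no viable d_min for the auto-selected MLE fit")
        return best
    if not isinstance(d_min, int) or d_min < 1:
        raise NetworkError(f"d_min must be >= 1, got {d_min}")
    pts = sorted((d, c) for d, c in histogram.items() if d >= d_min and c > 0)
    if len(pts) < 3:
        raise NetworkError(
            f"power-law fit needs >= 3 distinct degrees >= d_min, got {len(pts)}"
        )
    n_tail = sum(c for _, c in pts)
    if method == "ls":
        xs = [math.log(d) for d, _ in pts]
        ys = [math.log(c) for _, c in pts]
        n = len(xs)
        mx = sum(xs) / n
        my = sum(ys) / n
        sxx = sum((x - mx) ** 2 for x in xs)
        sxy = sum((x - mx) * (y - my) for x, y in zip(xs, ys))
        slope = sxy / sxx
        intercept = my - slope * mx
        ss_res = sum((y - (intercept + slope * x)) ** 2 for x, y in zip(xs, ys))
        ss_tot = sum((y - my) ** 2 for y in ys)
        if ss_tot > 0.0:
            r2 = 1.0 - ss_res / ss_tot
        else:
            r2 = 1.0 if ss_res < 1e-30 else 0.0
        return PowerLawFit(-slope, "ls", d_min, r2, n_tail)
    # discrete MLE (continuous-approximation form) with KS goodness
    log_sum = sum(c * math.log(d / (d_min - 0.5)) for d, c in pts)
    if log_sum <= 0.0:
        raise NetworkError("degenerate degree tail: all degrees at d_min")
    gamma = 1.0 + n_tail / log_sum
    cum = 0
    ks = 0.0
    for d, c in pts:
        cum += c
        ecdf = cum / n_tail
        model = 1.0 - (d + 0.5) ** (1.0 - gamma) / (d_min - 0.5) ** (1.0 - gamma)
        ks = max(ks, abs(ecdf - model))
    return PowerLawFit(gamma, "mle", d_min, ks, n_tail)


@dataclass(frozen=True)
class HubSet:
    """Degree-ranked hub genes with the selection rule that produced them."""

    genes: tuple[tuple[str, int], ...]  # (gene_id, degree), degree non-increasing
    rule: str
    param: float

    @property
    def gene_ids(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.genes)


def identify_hubs(
    network: GeneNetwork, rule: str = "top_fraction", param: float = 0.05
) -> HubSet:
    """Select hub genes by degree.

    rule "top_k": the param highest-degree genes; "top_fraction": the top
    param share of nodes (default 5%); "degree_threshold": all genes with
    degree >= param.  Ranking is by degree descending then gene_id; ties at
    the cutoff degree are all included.
    """
    if network.n_nodes == 0:
        raise NetworkError("cannot identify hubs in an empty network")
    ranked = sorted(network.degree.items(), key=lambda kv: (-kv[1], kv[0]))
    if rule == "top_k":
        k = int(param)
        if k < 1:
            raise NetworkError(f"top_k needs param >= 1, got {param}")
        k = min(k, len(ranked))
        cutoff = ranked[k - 1][1]
    elif rule == "top_fraction":
        if not (0.0 < param <= 1.0):
            raise NetworkError(f"top_fraction needs param in (0, 1], got {param}")
        k = max(1, round(param * len(ranked)))
        cutoff = ranked[k - 1][1]
    elif rule == "degree_threshold":
        if param < 0:
            raise NetworkError(f"degree_threshold needs param >= 0, got {param}")
        cutoff = param
    else:
        raise NetworkError(f"unknown hub rule {rule!r}")
    hubs = tuple((g, d) for g, d in ranked if d >= cutoff)
    return HubSet(genes=hubs, rule=rule, param=float(param))


def export_network(network: GeneNetwork, path: str | Path, fmt: str) -> Path:
    """Write the network as SIF, GraphML or edge-list TSV.

    GraphML carries relation types, evidence sources/details and co-citation
    p-values as edge attributes and round-trips through
    :func:`import_graphml` losslessly.
    """
    path = Path(path)
    if fmt == "sif":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for a, b, data in sorted(network.graph.edges(data=True)):
                fh.write(f"{a}\t{'|'.join(sorted(data['types']))}\t{b}\n")
        return path
    if fmt == "tsv":
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("gene_a\tgene_b\ttypes\tsources\tp_value\n")
            for a, b, data in sorted(network.graph.edges(data=True)):
                sources = "|".join(sorted({ev.source for ev in data["evidence"]}))
                pvals = [ev.p_value for ev in data["evidence"] if ev.p_value is not None]
                p = repr(min(pvals)) if pvals else ""
                fh.write(f"{a}\t{b}\t{'|'.join(sorted(data['types']))}\t{sources}\t{p}\n")
        return path
    if fmt == "graphml":
        out = nx.Graph()
        for a, b, data in network.graph.edges(data=True):
            attrs: dict[str, object] = {
                "types": "|".join(sorted(data["types"])),
                "evidence": ";".join(
                    f"{ev.source}~{ev.detail}~{'' if ev.p_value is None else repr(ev.p_value)}"
                    for ev in data["evidence"]
                ),
            }
            pvals = [ev.p_value for ev in data["evidence"] if ev.p_value is not None]
            if pvals:
                attrs["p_value"] = float(min(pvals))
            out.add_edge(a, b, **attrs)
        out.add_nodes_from(network.graph.nodes)
        nx.write_graphml(out, str(path))
        return path
    raise NetworkError(f"unknown export format {fmt!r}")


def import_graphml(path: str | Path) -> GeneNetwork:
    """Read a network previously written by :func:`export_network` (graphml)."""
    raw = nx.read_graphml(str(path))
    graph = nx.Graph()
    for a, b, data in raw.edges(data=True):
        types = tuple(sorted(data.get("types", "").split("|")))
        evidence: list[Evidence] = []
        for chunk in data.get("evidence", "").split(";"):
            if not chunk:
                continue
            source, detail, p_str = chunk.split("~")
            evidence.append(
                Evidence(source=source, detail=detail,
                         p_value=float(p_str) if p_str else None)
            )
        graph.add_edge(str(a), str(b), types=types, evidence=tuple(evidence))
    graph.add_nodes_from(str(n) for n in raw.nodes)
    return GeneNetwork(graph)
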