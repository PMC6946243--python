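"""Synthetic corpus, lexicon and relation-file generator with planted truth.

Stands in for a PubMed snapshot: every document is independently
disease-positive with probability ``disease_prevalence``; every gene is
mentioned with probability ``gene_mention_prob`` in background documents,
lifted to ``min(1, rho * gene_mention_prob)`` in disease documents for the
planted gene set.  A planted scale-free interaction graph (preferential
attachment) is realized twice: partitioned into ECrel/GErel KGML and PPrel
TSV relation files, and as sentence-level co-mentions in a fraction of
documents.  A fraction of gene mentions is emitted as conjunction patterns
("GEN-3/7") to exercise conjunction resolution.

Everything is deterministic under the seed: the same configuration produces
byte-identical files, and recounting the generated corpus with the real
pipeline reproduces the stored truth counts exactly.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .corpus_io import Corpus, Document, segment_sentences, write_corpus
from .ner import Lexicon, LexiconEntry, write_lexicon

__all__ = [
    "GeneratorConfig",
    "SyntheticTruth",
    "RecoveryReport",
    "DISEASE_TERMS",
    "generate_lexicon",
    "planted_interaction_graph",
    "generate_corpus",
    "generate_relation_files",
    "generate_gene_sets",
    "evaluate_recovery",
    "write_truth",
    "load_truth",
]

logger = logging.getLogger(__name__)

#: Disease phrase planted in disease-positive documents (and its match terms).
DISEASE_TERMS = ("bronchopulmonary dysplasia",)

# independent rng streams per stage so stages do not perturb each other
_STREAM_LEXICON = 1
_STREAM_GRAPH = 2
_STREAM_CORPUS = 3
_STREAM_GENESETS = 4

_FILLERS = (
    "Preterm infants requiring prolonged respiratory support were followed prospectively.",
    "Oxygen supplementation and ventilation records were reviewed for each admission.",
    "Histological assessment of alveolar septation was performed at discharge.",
    "Demographic covariates were balanced across the exposure groups.",
    "Longitudinal pulmonary function was recorded through the first year of life.",
)

_DISEASE_SENTENCE = "Several infants in this cohort developed bronchopulmonary dysplasia."


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic corpus.

    Defaults are the benchmark conditions used throughout the test suite:
    5000 documents over a 500-gene lexicon, 20% disease prevalence, 1%
    background mention probability per gene, 20 planted genes with an
    eight-fold mention enrichment in disease documents, and a planted
    preferential-attachment graph with 2 edges per arriving node.
    """

    seed: int
    n_docs: int = 5000
    n_genes: int = 500
    disease_prevalence: float = 0.2
    gene_mention_prob: float = 0.01
    n_planted: int = 20
    enrichment_factor: float = 8.0
    m_attach: int = 2
    comention_doc_fraction: float = 0.35
    n_filler_sentences: int = 2
    conjunction_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_docs < 1 or self.n_genes < 1:
            raise ValueError("n_docs and n_genes must be >= 1")
        for name in ("disease_prevalence", "gene_mention_prob"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0 <= self.n_planted <= self.n_genes):
            raise ValueError("n_planted must be in [0, n_genes]")
        if self.enrichment_factor < 1.0:
            raise ValueError("enrichment_factor must be >= 1")
        if not (0.0 <= self.comention_doc_fraction < 1.0):
            raise ValueError("comention_doc_fraction must be in [0, 1)")
        if not (0.0 <= self.conjunction_fraction < 1.0):
            raise ValueError("conjunction_fraction must be in [0, 1)")

    @property
    def planted_mention_prob(self) -> float:
        p = self.enrichment_factor * self.gene_mention_prob
        if p > 1.0:
            warnings.warn(
                "enrichment_factor * gene_mention_prob exceeds 1; clipping to 1",
                stacklevel=2,
            )
            return 1.0
        return p

    def gene_ids(self) -> list[str]:
        """Entrez-style numeric-string identifiers, 1001..1000+n_genes."""
        return [str(1000 + i) for i in range(1, self.n_genes + 1)]

    def symbols(self) -> list[str]:
        return [f"GEN{i}" for i in range(1, self.n_genes + 1)]

    def planted_genes(self) -> tuple[str, ...]:
        """Deterministic (seeded) sample of the planted associated genes."""
        if self.n_planted == 0:
            return ()
        rng = np.random.default_rng([self.seed, _STREAM_LEXICON])
        idx = rng.choice(self.n_genes, size=self.n_planted, replace=False)
        genes = self.gene_ids()
        return tuple(sorted(genes[i] for i in idx))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_docs": self.n_docs,
            "n_genes": self.n_genes,
            "disease_prevalence": self.disease_prevalence,
            "gene_mention_prob": self.gene_mention_prob,
            "n_planted": self.n_planted,
            "enrichment_factor": self.enrichment_factor,
            "m_attach": self.m_attach,
            "comention_doc_fraction": self.comention_doc_fraction,
            "n_filler_sentences": self.n_filler_sentences,
            "conjunction_fraction": self.conjunction_fraction,
        }


@dataclass
class SyntheticTruth:
    """Planted ground truth of one generated corpus.

    ``counts`` stores the realized document-level (m, k) for every gene in
    the lexicon; recounting the corpus with the pipeline must reproduce it
    exactly.
    """

    associated_genes: frozenset[str]
    planted_edges: frozenset[tuple[str, str]]
    counts: dict[str, tuple[int, int]]  # gene_id -> (m, k)
    N: int
    n: int
    seed: int


def generate_lexicon(config: GeneratorConfig) -> list[LexiconEntry]:
    """Synthetic gene lexicon: symbols GEN1..GENn with 0-3 synonyms each.

    Synonym forms are collision-free by construction (per-gene numbering) and
    include a spaced form ("gene 12") to exercise multi-token matching.
    """
    rng = np.random.default_rng([config.seed, _STREAM_LEXICON])
    entries: list[LexiconEntry] = []
    for i in range(1, config.n_genes + 1):
        pool = (f"GN{i}", f"gene {i}", f"GPX-{i}")
        n_syn = int(rng.integers(0, 4))
        entries.append(LexiconEntry(str(1000 + i), f"GEN{i}", pool[:n_syn]))
    return entries


def _pa_edges(n_nodes: int, m_attach: int, rng: np.random.Generator) -> list[tuple[int, int]]:
    """Preferential-attachment edge list over nodes 0..n_nodes-1.

    Convention: a seed dyad (nodes 0-1 joined by one edge); each arriving
    node attaches to min(m_attach, existing) distinct nodes sampled with
    probability proportional to degree.  Edge count is 1 + sum over arrivals,
    i.e. 1 + 2(n-2) for m_attach=2.
    """
    if m_attach < 1:
        raise ValueError(f"m_attach must be >= 1, got {m_attach}")
    if n_nodes < 2:
        raise ValueError(f"need >= 2 nodes, got {n_nodes}")
    edges: list[tuple[int, int]] = [(0, 1)]
    repeated: list[int] = [0, 1]  # node repeated once per incident edge end
    for v in range(2, n_nodes):
        m = min(m_attach, v)
        targets: set[int] = set()
        while len(targets) < m:
            targets.add(repeated[int(rng.integers(len(repeated)))])
        for t in sorted(targets):
            edges.append((t, v))
            repeated.extend((t, v))
    return edges


def planted_interaction_graph(config: GeneratorConfig) -> list[tuple[str, str]]:
    """The planted scale-free gene-gene edge set (canonically ordered pairs).

    Shared between the relation files and the corpus co-mention realization
    so that all evidence channels point at one coherent ground-truth graph.
    """
    rng = np.random.default_rng([config.seed, _STREAM_GRAPH])
    genes = config.gene_ids()
    edges = _pa_edges(config.n_genes, config.m_attach, rng)
    return [tuple(sorted((genes[a], genes[b]))) for a, b in edges]


def _gene_index(gene_id: str) -> int:
    return int(gene_id) - 1000


def generate_corpus(
    config: GeneratorConfig, lexicon_entries: Sequence[LexiconEntry] | None = None
) -> tuple[Corpus, SyntheticTruth]:
    """Generate the document corpus and its exact planted truth.

    Document model: bag of template sentences.  Disease-positive documents
    carry the disease phrase in one sentence; each mentioned gene appears in
    its own sentence, except co-mention pairs (one shared sentence realizing
    a planted edge) and conjunction pairs (an elided "GEN-i/j" form).
    """
    if lexicon_entries is None:
        lexicon_entries = generate_lexicon(config)
    by_id = {e.gene_id: e for e in lexicon_entries}
    genes = config.gene_ids()
    planted = set(config.planted_genes())
    edges = planted_interaction_graph(config) if config.m_attach >= 1 else []
    rng = np.random.default_rng([config.seed, _STREAM_CORPUS])

    # vectorized draws, one row per document
    disease_flags = rng.random(config.n_docs) < config.disease_prevalence
    u = rng.random((config.n_docs, config.n_genes))
    p_planted = config.planted_mention_prob
    planted_mask = np.array([g in planted for g in genes])

    docs: list[Document] = []
    gene_docs: dict[str, set[str]] = {g: set() for g in genes}
    disease_docs: set[str] = set()

    for d in range(config.n_docs):
        doc_id = f"D{d:05d}"
        is_disease = bool(disease_flags[d])
        thresh = np.where(
            planted_mask & is_disease, p_planted, config.gene_mention_prob
        )
        mentioned = {genes[j] for j in np.nonzero(u[d] < thresh)[0]}

        comention_pair: tuple[str, str] | None = None
        if edges and rng.random() < config.comention_doc_fraction:
            comention_pair = edges[int(rng.integers(len(edges)))]
            mentioned |= set(comention_pair)

        remaining = sorted(mentioned - set(comention_pair or ()))
        conjunction_pair: tuple[str, str] | None = None
        if len(remaining) >= 2 and rng.random() < config.conjunction_fraction:
            i, j = sorted(rng.choice(len(remaining), size=2, replace=False))
            conjunction_pair = (remaining[int(i)], remaining[int(j)])
            remaining = [g for g in remaining if g not in conjunction_pair]

        sentences: list[str] = []
        fillers = list(_FILLERS)
        for f in range(config.n_filler_sentences):
            sentences.append(fillers[int(rng.integers(len(fillers)))])
        if is_disease:
            sentences.append(_DISEASE_SENTENCE)
        if comention_pair is not None:
            a, b = comention_pair
            sentences.append(
                f"{by_id[a].symbol} interacted with {by_id[b].symbol} in alveolar tissue."
            )
        if conjunction_pair is not None:
            ia, ib = (_gene_index(g) for g in conjunction_pair)
            sentences.append(f"Levels of GEN-{ia}/{ib} were increased in severe cases.")
        for g in remaining:
            entry = by_id[g]
            surfaces = (entry.symbol,) + entry.synonyms
            surface = surfaces[int(rng.integers(len(surfaces)))]
            sentences.append(f"Expression of {surface} was markedly altered.")

        doc = segment_sentences(
            Document(
                doc_id=doc_id,
                title=f"Observational study {d:05d} of neonatal lung outcomes.",
                abstract=" ".join(sentences),
            )
        )
        docs.append(doc)
        if is_disease:
            disease_docs.add(doc_id)
        for g in mentioned:
            gene_docs[g].add(doc_id)

    counts = {
        g: (len(gene_docs[g]), len(gene_docs[g] & disease_docs)) for g in genes
    }
    truth = SyntheticTruth(
        associated_genes=frozenset(planted),
        planted_edges=frozenset(edges),
        counts=counts,
        N=config.n_docs,
        n=len(disease_docs),
        seed=config.seed,
    )
    return Corpus(docs), truth


def generate_relation_files(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Write the planted interaction graph as KGML (ECrel/GErel) + PPI TSV (PPrel).

    Edges of :func:`planted_interaction_graph` are partitioned uniformly at
    random (seeded) into the three relation categories.  Returns the paths
    keyed by "kgml" and "ppi".
    """
    if config.m_attach < 1:
        raise ValueError(f"m_attach must be >= 1, got {config.m_attach}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges = planted_interaction_graph(config)
    rng = np.random.default_rng([config.seed, _STREAM_GRAPH, 1])
    categories = rng.integers(0, 3, size=len(edges))  # 0=ECrel 1=GErel 2=PPrel

    kgml_path = outdir / "relations.kgml"
    genes_in_kgml = sorted(
        {g for e, c in zip(edges, categories) if c != 2 for g in e},
        key=_gene_index,
    )
    entry_id = {g: str(i + 1) for i, g in enumerate(genes_in_kgml)}
    lines = [
        '<?xml version="1.0"?>',
        '<pathway name="path:syn00001" org="syn" number="00001" title="synthetic planted pathway">',
    ]
    for g in genes_in_kgml:
        lines.append(f'  <entry id="{entry_id[g]}" name="syn:{g}" type="gene"/>')
    for (a, b), c in zip(edges, categories):
        if c == 2:
            continue
        rel = "ECrel" if c == 0 else "GErel"
        subtype = "compound" if rel == "ECrel" else "expression"
        lines.append(
            f'  <relation entry1="{entry_id[a]}" entry2="{entry_id[b]}" type="{rel}">'
            f'<subtype name="{subtype}" value="--&gt;"/></relation>'
        )
    lines.append("</pathway>")
    kgml_path.write_text("\n".join(lines) + "\n", encoding="utf-8")

    ppi_path = outdir / "ppi.tsv"
    with ppi_path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("#gene_a\tgene_b\n")
        for (a, b), c in zip(edges, categories):
            if c == 2:
                fh.write(f"{a}\t{b}\n")
    return {"kgml": kgml_path, "ppi": ppi_path}


def generate_gene_sets(
    config: GeneratorConfig, outdir: str | Path, *, n_terms_per_namespace: int = 12
) -> dict[str, Path]:
    """Write GMT gene-set files for BP/CC/MF/PATHWAY with one planted term each.

    Most terms are random draws from the lexicon; the planted term of each
    namespace contains the planted associated genes plus random padding, so
    enrichment of a well-recovered gene set finds it.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([config.seed, _STREAM_GENESETS])
    genes = config.gene_ids()
    planted = list(config.planted_genes())
    paths: dict[str, Path] = {}
    for ns in ("BP", "CC", "MF", "PATHWAY"):
        path = outdir / f"{ns.lower()}.gmt"
        with path.open("w", encoding="utf-8", newline="\n") as fh:
            for t in range(n_terms_per_namespace):
                size = int(rng.integers(15, 41))
                members = sorted(
                    (genes[i] for i in rng.choice(config.n_genes, size, replace=False)),
                    key=_gene_index,
                )
                fh.write(
                    f"{ns}:T{t:03d}\tsynthetic {ns} term {t}\t" + "\t".join(members) + "\n"
                )
            if planted:
                pad = sorted(
                    (genes[i] for i in rng.choice(config.n_genes, 10, replace=False)),
                    key=_gene_index,
                )
                members = sorted(set(planted) | set(pad), key=_gene_index)
                fh.write(
                    f"{ns}:PLANTED\tsynthetic planted {ns} term\t" + "\t".join(members) + "\n"
                )
        paths[ns] = path
    return paths


def write_truth(truth: SyntheticTruth, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "associated_genes": sorted(truth.associated_genes),
        "planted_edges": sorted(list(e) for e in truth.planted_edges),
        "counts": {g: list(mk) for g, mk in sorted(truth.counts.items())},
        "N": truth.N,
        "n": truth.n,
        "seed": truth.seed,
    }
    path.write_text(json.dumps(payload, sort_keys=True, indent=1) + "\n", encoding="utf-8")
    return path


def load_truth(path: str | Path) -> SyntheticTruth:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    return SyntheticTruth(
        associated_genes=frozenset(payload["associated_genes"]),
        planted_edges=frozenset(tuple(e) for e in payload["planted_edges"]),
        counts={g: (mk[0], mk[1]) for g, mk in payload["counts"].items()},
        N=payload["N"],
        n=payload["n"],
        seed=payload["seed"],
    )


@dataclass(frozen=True)
class RecoveryReport:
    """Recovery of planted signal: gene-level PR/FPR and edge-level Jaccard.

    ``precision`` is None (reported as NA) when nothing was predicted;
    ``edge_jaccard`` is None when no network was supplied.
    """

    precision: float | None
    recall: float | None
    fpr: float | None
    n_predicted: int
    n_planted: int
    n_tested: int
    edge_jaccard: float | None = None

    def to_dict(self) -> dict:
        def na(v):
            return "NA" if v is None else v

        return {
            "precision": na(self.precision),
            "recall": na(self.recall),
            "fpr": na(self.fpr),
            "n_predicted": self.n_predicted,
            "n_planted": self.n_planted,
            "n_tested": self.n_tested,
            "edge_jaccard": na(self.edge_jaccard),
        }


def evaluate_recovery(
    results: Sequence,
    truth: SyntheticTruth,
    network=None,
) -> RecoveryReport:
    """Score recovered associations (and optionally co-citation edges) vs truth.

    ``results`` is the output of score_all_genes on a generated corpus;
    ``network`` (optional) a merged GeneNetwork whose cocitation-typed edges
    are compared with the planted edge set by Jaccard index.
    """
    stray = [r.gene_id for r in results if r.gene_id not in truth.counts]
    if stray:
        raise ValueError(f"results reference genes absent from truth: {stray[:5]}")
    predicted = {r.gene_id for r in results if r.significant}
    tested = {r.gene_id for r in results}
    planted = truth.associated_genes
    tp = len(predicted & planted)
    fp = len(predicted - planted)
    precision = tp / len(predicted) if predicted else None
    recall = tp / len(planted) if planted else None
    nonplanted_tested = len(tested - planted)
    fpr = fp / nonplanted_tested if nonplanted_tested else None
    edge_jaccard = None
    if network is not None:
        cocit = {
            (a, b)
            for a, b, data in network.graph.edges(data=True)
            if "cocitation" in data["types"]
        }
        cocit = {tuple(sorted(e)) for e in cocit}
        union = cocit | truth.planted_edges
        edge_jaccard = len(cocit & truth.planted_edges) / len(union) if union else None
    return RecoveryReport(
        precision=precision,
        recall=recall,
        fpr=fpr,
        n_predicted=len(predicted),
        n_planted=len(planted),
        n_tested=len(tested),
        edge_jaccard=edge_jaccard,
    )


def write_synthetic_dataset(config: GeneratorConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full dataset bundle (corpus, lexicon, relations,
    gene sets, truth); returns the path of every artifact."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = generate_lexicon(config)
    corpus, truth = generate_corpus(config, entries)
    paths = {
        "lexicon": write_lexicon(entries, outdir / "lexicon.tsv"),
        "corpus": write_corpus(corpus, outdir / "corpus.jsonl"),
        "truth": write_truth(truth, outdir / "truth.json"),
    }
    paths.update(generate_relation_files(config, outdir))
    gmt = generate_gene_sets(config, outdir)
    paths.update({f"gmt_{ns.lower()}": p for ns, p in gmt.items()})
    return paths
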