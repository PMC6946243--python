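"""End-to-end orchestration: mine -> enrich -> network -> report.

A single :class:`PipelineConfig` (loadable from YAML) drives all stages with
the analysis thresholds surfaced as named keys (association alpha, enrichment
alpha, co-citation alpha and support, tail convention, hub rule).  Every run
writes a manifest (config hash, seed, per-stage in/out counts) and all
artifacts deterministically: re-running the same config reproduces every
output byte-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from . import __version__
from .cooccurrence import (
    AssociationResult,
    count_gene_disease,
    score_all_genes,
    write_results_tsv,
)
from .corpus_io import Corpus, parse_plaintext_corpus, parse_pubmed_xml
from .enrichment import (
    EnrichmentResult,
    annotated_background,
    enrich,
    load_gaf,
    load_gmt,
    summarize_by_namespace,
    write_enrichment_tsv,
)
from .ner import Lexicon, Mention, load_lexicon, tag_corpus, write_mentions
from .network import (
    GeneNetwork,
    cocitation_edges,
    degree_histogram,
    export_network,
    fit_power_law,
    identify_hubs,
    load_ppi_table,
    merge_network,
    parse_kgml,
)

__all__ = [
    "PipelineConfig",
    "PipelineStageError",
    "MineOutput",
    "run_mine",
    "run_enrich",
    "run_network",
    "run_all",
]

logger = logging.getLogger(__name__)


class PipelineStageError(RuntimeError):
    """A stage failed; carries the stage name for the funnel log."""

    def __init__(self, stage: str, cause: Exception) -> None:
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass(frozen=True)
class AnnotationSpec:
    path: str
    format: str  # "gmt" | "gaf"
    namespace: str = "PATHWAY"  # used by gmt only


@dataclass(frozen=True)
class PipelineConfig:
    """All inputs, thresholds and switches for one pipeline run."""

    corpus: str
    lexicon: str
    outdir: str
    disease_terms: tuple[str, ...] = ("bronchopulmonary dysplasia",)
    stoplist: str | None = None
    annotations: tuple[AnnotationSpec, ...] = ()
    kgml: tuple[str, ...] = ()
    ppi: tuple[str, ...] = ()
    alpha_association: float = 0.05
    alpha_enrichment: float = 0.05
    alpha_cocitation: float = 0.05
    cocitation_min_support: int = 2
    strict_tail: bool = False
    correction: str | None = None
    hub_rule: str = "top_fraction"
    hub_param: float = 0.05
    include_title: bool = True
    network_restriction: str = "none"  # none | significant | significant_plus_neighbors
    seed: int = 0

    def validate(self) -> None:
        for alpha in (self.alpha_association, self.alpha_enrichment, self.alpha_cocitation):
            if not (0.0 < alpha < 1.0):
                raise ValueError(f"alpha values must be in (0, 1), got {alpha}")
        if not self.disease_terms:
            raise ValueError("disease_terms must be non-empty")
        if self.network_restriction not in ("none", "significant", "significant_plus_neighbors"):
            raise ValueError(f"unknown network_restriction {self.network_restriction!r}")
        missing = [
            p
            for p in (
                [self.corpus, self.lexicon]
                + ([self.stoplist] if self.stoplist else [])
                + [a.path for a in self.annotations]
                + list(self.kgml)
                + list(self.ppi)
            )
            if not Path(p).exists()
        ]
        if missing:
            raise FileNotFoundError(f"configured paths do not exist: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        annotations = tuple(
            AnnotationSpec(
                path=a["path"],
                format=a.get("format", "gmt"),
                namespace=a.get("namespace", "PATHWAY"),
            )
            for a in raw.pop("annotations", [])
        )
        raw["annotations"] = annotations
        for key in ("disease_terms", "kgml", "ppi"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["annotations"] = [dataclasses.asdict(a) for a in self.annotations]
        d["disease_terms"] = list(self.disease_terms)
        d["kgml"] = list(self.kgml)
        d["ppi"] = list(self.ppi)
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _load_corpus(path: str) -> Corpus:
    if path.endswith(".xml"):
        return parse_pubmed_xml(path)
    return parse_plaintext_corpus(path)


@dataclass
class MineOutput:
    corpus: Corpus
    lexicon: Lexicon
    mentions: list[Mention]
    results: list[AssociationResult]

    @property
    def significant_genes(self) -> set[str]:
        return {r.gene_id for r in self.results if r.significant}


def run_mine(config: PipelineConfig) -> MineOutput:
    """Literature-mining stage: parse -> segment -> tag -> resolve -> count -> score.

    Writes ``mine/associations.tsv`` and ``mine/mentions.tsv`` under the
    configured output directory.
    """
    config.validate()
    outdir = Path(config.outdir) / "mine"
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        lexicon = load_lexicon(config.lexicon, config.stoplist)
        corpus = _load_corpus(config.corpus)
        mentions = tag_corpus(corpus, lexicon, include_title=config.include_title)
        counts = count_gene_disease(
            corpus, mentions, config.disease_terms, include_title=config.include_title
        )
        results = score_all_genes(
            counts,
            config.alpha_association,
            correction=config.correction,
            strict_tail=config.strict_tail,
        )
    except Exception as exc:  # noqa: BLE001 - stage name is the contract
        raise PipelineStageError("mine", exc) from exc
    write_results_tsv(results, outdir / "associations.tsv", lexicon)
    write_mentions(mentions, outdir / "mentions.tsv")
    logger.info(
        "mine: %d documents -> %d mentions -> %d genes -> %d significant",
        corpus.size, len(mentions), len(results), len([r for r in results if r.significant]),
    )
    return MineOutput(corpus=corpus, lexicon=lexicon, mentions=mentions, results=results)


def run_enrich(
    config: PipelineConfig, significant_genes: set[str]
) -> list[EnrichmentResult] | None:
    """Enrichment stage; returns None (skipped, logged) without annotations."""
    if not config.annotations:
        logger.info("enrich: no annotation files configured, stage skipped")
        return None
    outdir = Path(config.outdir) / "enrich"
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        annotations = []
        for spec in config.annotations:
            if spec.format == "gmt":
                annotations.extend(load_gmt(spec.path, spec.namespace))
            elif spec.format == "gaf":
                annotations.extend(load_gaf(spec.path))
            else:
                raise ValueError(f"unknown annotation format {spec.format!r}")
        background = annotated_background(annotations)
        query = significant_genes & background
        dropped = len(significant_genes) - len(query)
        if dropped:
            logger.info("enrich: %d significant genes have no annotation", dropped)
        results = enrich(query, background, annotations, config.alpha_enrichment)
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("enrich", exc) from exc
    write_enrichment_tsv(results, outdir / "enrichment.tsv")
    groups = summarize_by_namespace(results)
    with (outdir / "namespace_summary.tsv").open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("namespace\tn_significant\tterm_ids\n")
        for ns, terms in groups.items():
            fh.write(f"{ns}\t{len(terms)}\t{','.join(t.term_id for t in terms)}\n")
    logger.info(
        "enrich: %d terms tested, %d significant",
        len(results), sum(len(v) for v in groups.values()),
    )
    return results


@dataclass
class NetworkOutput:
    network: GeneNetwork
    histogram: dict[int, int] | None
    fit: object | None
    hubs: object | None


def run_network(config: PipelineConfig, mine: MineOutput) -> NetworkOutput:
    """Network stage: curated relations + co-citation, topology, hubs, exports.

    With an empty significant-gene set the network falls back to co-citation
    over all mentioned genes (no restriction), which is the documented
    behavior for under-powered corpora.
    """
    outdir = Path(config.outdir) / "network"
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        edge_lists = []
        for path in config.kgml:
            edge_lists.append(parse_kgml(path))
        for path in config.ppi:
            edge_lists.append(load_ppi_table(path, valid_genes=mine.lexicon.gene_ids))
        edge_lists.append(
            cocitation_edges(
                mine.corpus,
                mine.mentions,
                config.alpha_cocitation,
                min_support=config.cocitation_min_support,
                strict_tail=config.strict_tail,
            )
        )
        significant = mine.significant_genes
        restrict_to = None
        restrict_mode = "both"
        if significant and config.network_restriction == "significant":
            restrict_to = significant
        elif significant and config.network_restriction == "significant_plus_neighbors":
            restrict_to, restrict_mode = significant, "any"
        network = merge_network(
            *edge_lists, restrict_to=restrict_to, restrict_mode=restrict_mode
        )
        histogram = fit = hubs = None
        if network.n_nodes > 0:
            histogram = degree_histogram(network)
            try:
                fit = fit_power_law(histogram)
            except Exception:
                logger.info("network: degree support too small for a power-law fit")
            hubs = identify_hubs(network, config.hub_rule, config.hub_param)
    except PipelineStageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineStageError("network", exc) from exc
    export_network(network, outdir / "network.sif", "sif")
    export_network(network, outdir / "network.graphml", "graphml")
    export_network(network, outdir / "network.tsv", "tsv")
    if histogram is not None:
        with (outdir / "degree_histogram.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("degree\tn_nodes\n")
            for d, c in histogram.items():
                fh.write(f"{d}\t{c}\n")
    if fit is not None:
        (outdir / "powerlaw.json").write_text(
            json.dumps(
                {
                    "exponent": fit.exponent,
                    "method": fit.method,
                    "d_min": fit.d_min,
                    "goodness": fit.goodness,
                    "n_tail": fit.n_tail,
                    "is_power_law": fit.is_power_law,
                },
                sort_keys=True,
                indent=1,
            )
            + "\n",
            encoding="utf-8",
        )
    if hubs is not None:
        with (outdir / "hubs.tsv").open("w", encoding="utf-8", newline="\n") as fh:
            fh.write("rank\tgene_id\tsymbol\tdegree\n")
            for rank, (gene, deg) in enumerate(hubs.genes, start=1):
                symbol = (
                    mine.lexicon.symbol_of(gene) if gene in mine.lexicon else gene
                )
                fh.write(f"{rank}\t{gene}\t{symbol}\t{deg}\n")
    logger.info(
        "network: %d nodes, %d edges, %d hubs",
        network.n_nodes, network.n_edges,
        len(hubs.genes) if hubs is not None else 0,
    )
    return NetworkOutput(network=network, histogram=histogram, fit=fit, hubs=hubs)


def run_all(config: PipelineConfig) -> dict:
    """Full pipeline (mine -> enrich -> network) with a run manifest.

    Returns a summary dict mirroring ``manifest.json``.  Stage failures
    propagate as :class:`PipelineStageError`; outputs of completed stages are
    preserved and the manifest is still written with the failure flagged.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_sha256": config.content_hash(),
        "seed": config.seed,
        "litnet_version": __version__,
        "stages": {},
        "failed_stage": None,
    }
    try:
        mine = run_mine(config)
        n_sig = len(mine.significant_genes)
        manifest["stages"]["mine"] = {
            "documents": mine.corpus.size,
            "mentions": len(mine.mentions),
            "genes_scored": len(mine.results),
            "significant_genes": n_sig,
        }
        enr = run_enrich(config, mine.significant_genes)
        if enr is None:
            manifest["stages"]["enrich"] = {"skipped": True}
        else:
            manifest["stages"]["enrich"] = {
                "terms_tested": len(enr),
                "significant_terms": sum(1 for r in enr if r.significant),
            }
        net = run_network(config, mine)
        manifest["stages"]["network"] = {
            "nodes": net.network.n_nodes,
            "edges": net.network.n_edges,
            "hubs": len(net.hubs.genes) if net.hubs is not None else 0,
            "powerlaw_exponent": net.fit.exponent if net.fit is not None else None,
        }
    except PipelineStageError as exc:
        manifest["failed_stage"] = exc.stage
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8"
        )
        raise
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, sort_keys=True, indent=1) + "\n", encoding="utf-8"
    )
    return manifest
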