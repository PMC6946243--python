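"""Network construction, topology analysis, hubs and exports."""

from __future__ import annotations

import random

import pytest

from litnet.corpus_io import Corpus
from litnet.ner import tag_corpus
from litnet.network import (
    Evidence,
    NetworkError,
    cocitation_edges,
    degree_histogram,
    export_network,
    fit_power_law,
    identify_hubs,
    import_graphml,
    load_ppi_table,
    merge_network,
    parse_kgml,
    relation_edge,
)

from conftest import make_doc

KGML = """<?xml version="1.0"?>
<pathway name="path:syn1" org="syn" number="1">
  <entry id="1" name="syn:100" type="gene"/>
  <entry id="2" name="syn:200" type="gene"/>
  <entry id="3" name="cpd:C00001" type="compound"/>
  <entry id="4" name="syn:300 syn:400" type="gene"/>
  <relation entry1="1" entry2="2" type="PPrel"><subtype name="binding" value="--"/></relation>
  <relation entry1="1" entry2="3" type="ECrel"><subtype name="compound" value="3"/></relation>
  <relation entry1="2" entry2="4" type="GErel"><subtype name="expression" value="--&gt;"/></relation>
  <relation entry1="1" entry2="2" type="PPrel"><subtype name="binding" value="--"/></relation>
</pathway>
"""


class TestParsers:
    def test_kgml_gene_relations_only(self, tmp_path):
        path = tmp_path / "p.kgml"
        path.write_text(KGML)
        edges = parse_kgml(path)
        pairs = {(e.gene_a, e.gene_b, e.relation_type) for e in edges}
        # duplicate PPrel deduplicated; compound relation skipped;
        # multi-gene entry expands to two GErel edges
        assert pairs == {
            ("100", "200", "PPrel"),
            ("200", "300", "GErel"),
            ("200", "400", "GErel"),
        }

    def test_ppi_table_canonicalizes_and_drops_self_loops(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("#a\tb\nA\tB\nB\tA\nC\tC\nA\tX\n")
        edges = load_ppi_table(path, valid_genes={"A", "B", "C"})
        assert len(edges) == 1
        assert edges[0].pair == ("A", "B")
        assert edges[0].relation_type == "PPrel"

    def test_ppi_without_lexicon_keeps_all_valid_rows(self, tmp_path):
        path = tmp_path / "ppi.tsv"
        path.write_text("A\tB\nC\tD\nE\tF\n")
        assert len(load_ppi_table(path)) == 3


DISEASE_FREE_FILLER = "Nothing to report in this sentence."


class TestCocitation:
    def make_corpus(self, n_docs, joint_docs, lexicon):
        """Corpus with one filler + optionally one joint IL6/TNF sentence per doc."""
        docs = []
        for i in range(n_docs):
            if i < joint_docs:
                body = f"{DISEASE_FREE_FILLER} IL6 binds TNF here."
            else:
                body = f"{DISEASE_FREE_FILLER} {DISEASE_FREE_FILLER}"
            docs.append(make_doc(str(i), "", body))
        return Corpus(docs)

    def test_exclusive_pair_probability(self, cytokine_lexicon):
        # 3 joint sentences among 30 total: p = 1 / C(30,3) = 1/4060
        corpus = Corpus(
            [
                make_doc(
                    str(i),
                    "",
                    "IL6 binds TNF strongly." if i < 3 else DISEASE_FREE_FILLER,
                )
                for i in range(30)
            ]
        )
        mentions = tag_corpus(corpus, cytokine_lexicon)
        (edge,) = cocitation_edges(corpus, mentions, alpha=0.05)
        assert edge.relation_type == "cocitation"
        (ev,) = edge.evidence
        assert ev.p_value == pytest.approx(1 / 4060, abs=1e-12)

    def test_never_cooccurring_pair_yields_no_edge(self, cytokine_lexicon):
        corpus = Corpus(
            [make_doc("1", "", "IL6 alone."), make_doc("2", "", "TNF alone.")]
        )
        mentions = tag_corpus(corpus, cytokine_lexicon)
        assert cocitation_edges(corpus, mentions) == []

    def test_min_support_suppresses_single_sentence_pairs(self, cytokine_lexicon):
        corpus = Corpus(
            [make_doc("0", "", "IL6 binds TNF here.")]
            + [make_doc(str(i), "", DISEASE_FREE_FILLER) for i in range(1, 40)]
        )
        mentions = tag_corpus(corpus, cytokine_lexicon)
        # k'=1 is individually significant in 40 sentences but below support
        assert cocitation_edges(corpus, mentions, min_support=2) == []
        assert len(cocitation_edges(corpus, mentions, min_support=1)) == 1


def random_edge_list(rng: random.Random, n_genes=12, n_edges=15):
    edges = []
    for _ in range(n_edges):
        a, b = rng.sample([f"g{i:02d}" for i in range(n_genes)], 2)
        rel = rng.choice(["ECrel", "PPrel", "GErel"])
        edges.append(relation_edge(a, b, rel, [Evidence(source=f"src{rng.randint(0,2)}")]))
    return edges


class TestMerge:
    def test_multi_source_pair_collapses_to_one_edge(self):
        e1 = relation_edge("A", "B", "PPrel", [Evidence(source="ppi")])
        e2 = relation_edge("B", "A", "cocitation", [Evidence(source="lit", p_value=0.01)])
        net = merge_network([e1], [e2])
        assert net.n_edges == 1
        data = net.graph.edges["A", "B"]
        assert set(data["types"]) == {"PPrel", "cocitation"}
        assert len(data["evidence"]) == 2

    def test_disjoint_lists_union(self):
        rng = random.Random(0)
        l1, l2 = random_edge_list(rng, n_edges=2), random_edge_list(rng, n_edges=3)
        pairs = {e.pair for e in l1} | {e.pair for e in l2}
        assert merge_network(l1, l2).n_edges == len(pairs)

    def test_empty_input_gives_empty_network(self):
        net = merge_network([])
        assert net.n_nodes == net.n_edges == 0
        with pytest.raises(NetworkError):
            degree_histogram(net)

    def test_merge_commutative_and_idempotent(self):
        for seed in range(50):
            rng = random.Random(seed)
            l1, l2 = random_edge_list(rng), random_edge_list(rng)
            assert merge_network(l1, l2) == merge_network(l2, l1)
            assert merge_network(l1, l1) == merge_network(l1)

    def test_handshake_lemma(self):
        for seed in range(50):
            rng = random.Random(1000 + seed)
            net = merge_network(random_edge_list(rng), random_edge_list(rng))
            assert sum(net.degree.values()) == 2 * net.n_edges

    def test_restriction_modes(self):
        edges = [
            relation_edge("A", "B", "PPrel"),
            relation_edge("B", "C", "PPrel"),
            relation_edge("C", "D", "PPrel"),
        ]
        both = merge_network(edges, restrict_to={"A", "B"}, restrict_mode="both")
        assert both.edge_pairs() == {("A", "B")}
        any_ = merge_network(edges, restrict_to={"A", "B"}, restrict_mode="any")
        assert any_.edge_pairs() == {("A", "B"), ("B", "C")}


class TestTopology:
    def test_degree_histogram_examples(self):
        triangle = merge_network(
            [
                relation_edge("a", "b", "PPrel"),
                relation_edge("b", "c", "PPrel"),
                relation_edge("a", "c", "PPrel"),
            ]
        )
        assert degree_histogram(triangle) == {2: 3}
        star = merge_network(
            [relation_edge("hub", leaf, "PPrel") for leaf in "wxyz"]
        )
        assert degree_histogram(star) == {1: 4, 4: 1}
        path = merge_network(
            [relation_edge("a", "b", "PPrel"), relation_edge("b", "c", "PPrel")]
        )
        assert degree_histogram(path) == {1: 2, 2: 1}

    def test_exactly_collinear_fit_is_machine_precise(self):
        # counts 512 d^-3: perfectly collinear in log-log space
        fit = fit_power_law({1: 512, 2: 64, 4: 8, 8: 1})
        assert fit.exponent == pytest.approx(3.0, abs=1e-12)
        assert fit.goodness == pytest.approx(1.0, abs=1e-12)
        assert fit.is_power_law

    def test_uniform_counts_flagged_non_power_law(self):
        fit = fit_power_law({1: 5, 2: 5, 3: 5, 4: 5})
        assert fit.exponent == pytest.approx(0.0, abs=1e-12)
        assert not fit.is_power_law

    def test_too_few_support_points_rejected(self):
        with pytest.raises(NetworkError):
            fit_power_law({1: 10, 2: 5})

    def test_mle_mode_recovers_steep_exponent(self):
        # geometric-ish tail c(d) = round(1000 * d^-3) for d=2..20
        hist = {d: max(1, round(1000 * d**-3.0)) for d in range(2, 21)}
        fit = fit_power_law(hist, method="mle", d_min=2)
        assert 2.5 <= fit.exponent <= 3.5


class TestHubs:
    def star(self):
        return merge_network(
            [relation_edge("hub", leaf, "PPrel") for leaf in "wxyz"]
        )

    def degrees_53221(self):
        # degrees: a=5? build explicit degree sequence [5,5,3,2,1] is not
        # graphical with 5 nodes; use top_k semantics on a simple graph
        edges = [
            relation_edge("a", x, "PPrel") for x in ["b", "c", "d", "e", "f"]
        ] + [
            relation_edge("b", x, "PPrel") for x in ["c", "d", "e", "f"]
        ] + [relation_edge("c", "d", "PPrel")]
        return merge_network(edges)

    def test_star_top1_is_center(self):
        hubs = identify_hubs(self.star(), "top_k", 1)
        assert hubs.gene_ids == ("hub",)

    def test_top_k_includes_cutoff_ties(self):
        net = self.degrees_53221()
        # degrees: a=5, b=5, c=3, d=3, e=2, f=2
        hubs = identify_hubs(net, "top_k", 2)
        assert hubs.gene_ids == ("a", "b")
        hubs3 = identify_hubs(net, "top_k", 3)
        assert hubs3.gene_ids == ("a", "b", "c", "d")  # tie at degree 3 included

    def test_degree_threshold(self):
        net = self.degrees_53221()
        hubs = identify_hubs(net, "degree_threshold", 3)
        assert hubs.gene_ids == ("a", "b", "c", "d")

    def test_degrees_nonincreasing_and_stable_under_relabeling(self):
        rng = random.Random(5)
        edges = random_edge_list(rng, n_genes=20, n_edges=40)
        net = merge_network(edges)
        hubs = identify_hubs(net, "top_fraction", 0.25)
        degs = [d for _, d in hubs.genes]
        assert degs == sorted(degs, reverse=True)
        # relabel nodes with a degree-preserving prefix swap
        relabeled = [
            relation_edge("x" + e.gene_a, "x" + e.gene_b, e.relation_type, e.evidence)
            for e in edges
        ]
        hubs2 = identify_hubs(merge_network(relabeled), "top_fraction", 0.25)
        assert [("x" + g, d) for g, d in hubs.genes] == list(hubs2.genes)

    def test_invalid_param_rejected(self):
        with pytest.raises(NetworkError):
            identify_hubs(self.star(), "top_fraction", 1.5)
        with pytest.raises(NetworkError):
            identify_hubs(self.star(), "nonsense", 1)


class TestExport:
    def test_sif_single_edge(self, tmp_path):
        net = merge_network([relation_edge("A", "B", "PPrel")])
        path = export_network(net, tmp_path / "n.sif", "sif")
        assert path.read_text().splitlines() == ["A\tPPrel\tB"]

    def test_graphml_round_trip_preserves_structure_and_attributes(self, tmp_path):
        for seed in range(50):
            rng = random.Random(seed)
            cocit = [
                relation_edge(
                    *rng.sample(["g1", "g2", "g3", "g4"], 2),
                    "cocitation",
                    [Evidence(source="cocitation", detail="k=3", p_value=rng.random())],
                )
            ]
            net = merge_network(random_edge_list(rng, n_genes=8), cocit)
            path = export_network(net, tmp_path / f"n{seed}.graphml", "graphml")
            assert import_graphml(path) == net

    def test_empty_network_exports_valid_files(self, tmp_path):
        net = merge_network([])
        assert export_network(net, tmp_path / "e.sif", "sif").read_text() == ""
        assert import_graphml(
            export_network(net, tmp_path / "e.graphml", "graphml")
        ) == net

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(NetworkError):
            export_network(merge_network([]), tmp_path / "x", "gexf")
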