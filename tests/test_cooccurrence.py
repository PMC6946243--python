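"""Hypergeometric tail statistic and gene-disease counting."""

from __future__ import annotations

import math
import random
from fractions import Fraction

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from litnet.cooccurrence import (
    CooccurrenceCounts,
    count_gene_disease,
    hypergeom_tail,
    rank_by_frequency,
    score_all_genes,
)
from litnet.corpus_io import Corpus
from litnet.ner import tag_corpus

from conftest import make_doc


def exact_tail(k: int, m: int, n: int, N: int) -> Fraction:
    """Independent big-integer oracle: direct pmf enumeration."""
    num = sum(math.comb(m, i) * math.comb(N - m, n - i) for i in range(k, min(m, n) + 1))
    return Fraction(num, math.comb(N, n))


def random_counts(rng: random.Random, n_max: int) -> tuple[int, int, int, int]:
    N = rng.randint(1, n_max)
    m = rng.randint(0, N)
    n = rng.randint(0, N)
    k = rng.randint(0, min(m, n))
    return k, m, n, N


class TestHypergeomTail:
    def test_known_exact_values(self):
        assert hypergeom_tail(2, 4, 5, 20) == pytest.approx(241 / 969, abs=1e-12)
        assert hypergeom_tail(3, 3, 3, 30) == pytest.approx(1 / 4060, abs=1e-12)

    def test_zero_overlap_gives_one(self):
        assert hypergeom_tail(0, 4, 5, 20) == 1.0
        assert hypergeom_tail(0, 0, 0, 7) == 1.0

    def test_saturated_overlap(self):
        # m = n = N: the overlap is always N, so P(X >= N) = 1
        assert hypergeom_tail(5, 5, 5, 5) == 1.0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            hypergeom_tail(3, 2, 5, 20)  # k > min(m, n)
        with pytest.raises(ValueError):
            hypergeom_tail(0, 21, 5, 20)  # m > N
        with pytest.raises(ValueError):
            hypergeom_tail(0, 1, 1, 0)  # empty universe

    def test_strict_tail_shifts_by_one(self):
        p_inclusive = hypergeom_tail(3, 4, 5, 20)
        assert hypergeom_tail(2, 4, 5, 20, strict=True) == pytest.approx(
            p_inclusive, abs=1e-15
        )
        assert hypergeom_tail(4, 4, 5, 20, strict=True) == 0.0

    def test_agrees_with_exact_oracle_on_random_tuples(self):
        rng = random.Random(20240917)
        for _ in range(400):
            k, m, n, N = random_counts(rng, 60)
            expected = float(exact_tail(k, m, n, N))
            assert hypergeom_tail(k, m, n, N) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy_at_large_N(self):
        from scipy.stats import hypergeom as sp_hypergeom

        rng = random.Random(11)
        for _ in range(50):
            k, m, n, N = random_counts(rng, 100_000)
            ours = hypergeom_tail(k, m, n, N)
            theirs = float(sp_hypergeom.sf(k - 1, N, m, n))
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    @given(st.integers(1, 40), st.data())
    @settings(max_examples=150, deadline=None, derandomize=True)
    def test_nonincreasing_in_k_and_symmetric(self, N, data):
        m = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        previous = 1.0
        for k in range(min(m, n) + 1):
            p = hypergeom_tail(k, m, n, N)
            assert p <= previous + 1e-12
            assert p == pytest.approx(hypergeom_tail(k, n, m, N), abs=1e-12)
            previous = p

    @given(st.integers(1, 50), st.data())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_pmf_sums_to_one(self, N, data):
        m = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        lo = max(0, m + n - N)
        total = sum(
            hypergeom_tail(k, m, n, N) - hypergeom_tail(k, m, n, N, strict=True)
            for k in range(lo, min(m, n) + 1)
        )
        assert total == pytest.approx(1.0, abs=1e-12)


DISEASE = ("bronchopulmonary dysplasia",)


def four_doc_corpus():
    # gene IL6 in docs 1,2; disease in docs 2,3
    return Corpus(
        [
            make_doc("1", "", "IL6 was elevated."),
            make_doc("2", "", "IL6 in bronchopulmonary dysplasia."),
            make_doc("3", "", "Infants with bronchopulmonary dysplasia."),
            make_doc("4", "", "Nothing relevant here."),
        ]
    )


class TestCounting:
    def test_document_level_set_intersection(self, cytokine_lexicon):
        corpus = four_doc_corpus()
        mentions = tag_corpus(corpus, cytokine_lexicon)
        counts = count_gene_disease(corpus, mentions, DISEASE)
        c = counts["3569"]  # IL6
        assert (c.N, c.m, c.n, c.k) == (4, 2, 2, 1)

    def test_repeated_mentions_count_once_per_document(self, cytokine_lexicon):
        corpus = Corpus(
            [make_doc("1", "IL6 title", "IL6 again. And IL-6 once more.")]
        )
        mentions = tag_corpus(corpus, cytokine_lexicon)
        counts = count_gene_disease(corpus, mentions, DISEASE, genes=["3569"])
        assert counts["3569"].m == 1

    def test_absent_gene_counts_zero(self, cytokine_lexicon):
        corpus = four_doc_corpus()
        mentions = tag_corpus(corpus, cytokine_lexicon)
        counts = count_gene_disease(corpus, mentions, DISEASE, genes=["7124"])
        assert (counts["7124"].m, counts["7124"].k) == (0, 0)

    def test_empty_corpus_refused(self, cytokine_lexicon):
        with pytest.raises(ValueError):
            count_gene_disease(Corpus([]), [], DISEASE)

    def test_n_identical_across_genes(self, cytokine_lexicon):
        corpus = four_doc_corpus()
        mentions = tag_corpus(corpus, cytokine_lexicon)
        counts = count_gene_disease(corpus, mentions, DISEASE, genes=["3569", "7124"])
        assert counts["3569"].n == counts["7124"].n == 2


class TestScoring:
    def test_zero_overlap_never_significant(self):
        counts = {"g": CooccurrenceCounts(N=100, n=10, m=5, k=0)}
        (res,) = score_all_genes(counts, alpha=0.04999)
        assert res.p_value == 1.0
        assert not res.significant

    def test_tie_break_by_k_then_gene_id(self):
        counts = {
            # same p (k=0 -> p=1) except b has larger k via different m/n
            "b": CooccurrenceCounts(N=10, n=0, m=3, k=0),
            "a": CooccurrenceCounts(N=10, n=0, m=2, k=0),
            "c": CooccurrenceCounts(N=10, n=0, m=1, k=0),
        }
        order = [r.gene_id for r in score_all_genes(counts)]
        assert order == ["a", "b", "c"]  # p and k all tie -> lexicographic

    def test_results_sorted_ascending_p(self):
        counts = {
            "weak": CooccurrenceCounts(N=100, n=20, m=10, k=3),
            "strong": CooccurrenceCounts(N=100, n=20, m=10, k=9),
        }
        results = score_all_genes(counts)
        assert [r.gene_id for r in results] == ["strong", "weak"]
        assert results[0].p_value < results[1].p_value

    def test_genes_without_mentions_excluded(self):
        counts = {"absent": CooccurrenceCounts(N=10, n=2, m=0, k=0)}
        assert score_all_genes(counts) == []

    def test_bh_mode_is_more_conservative(self):
        counts = {
            f"g{i}": CooccurrenceCounts(N=1000, n=100, m=20, k=k)
            for i, k in enumerate([2, 3, 4, 5, 6, 7])
        }
        raw = {r.gene_id for r in score_all_genes(counts) if r.significant}
        bh = {
            r.gene_id
            for r in score_all_genes(counts, correction="bh")
            if r.significant
        }
        assert bh <= raw

    def test_rank_by_frequency(self):
        counts = {
            "A": CooccurrenceCounts(N=10, n=8, m=7, k=7),
            "B": CooccurrenceCounts(N=10, n=8, m=3, k=3),
            "C": CooccurrenceCounts(N=10, n=8, m=3, k=3),
        }
        assert rank_by_frequency(counts, 1) == ["A"]
        assert rank_by_frequency(counts, 10) == ["A", "B", "C"]  # tie by gene_id
        with pytest.raises(ValueError):
            rank_by_frequency(counts, 0)

    def test_reported_frequency_order_emerges_from_replayed_rates(self, cytokine_lexicon):
        """Replaying the relative citation rates of the four most-cited genes
        (VEGFA > IL6 > TNF > IL1B-like proxy INS) reproduces their ranking."""
        rng = random.Random(3)
        docs = []
        rates = {"VEGFA": 0.30, "IL6": 0.22, "TNF": 0.15, "INS": 0.08}
        for i in range(400):
            body = ["A cohort with bronchopulmonary dysplasia."]
            for symbol, rate in rates.items():
                if rng.random() < rate:
                    body.append(f"{symbol} was measured.")
            docs.append(make_doc(str(i), "", " ".join(body)))
        corpus = Corpus(docs)
        mentions = tag_corpus(corpus, cytokine_lexicon)
        counts = count_gene_disease(corpus, mentions, DISEASE)
        ranked = rank_by_frequency(counts, 4)
        symbols = [cytokine_lexicon.symbol_of(g) for g in ranked]
        assert symbols == ["VEGFA", "IL6", "TNF", "INS"]
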