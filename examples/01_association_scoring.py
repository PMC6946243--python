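"""Score gene-disease associations in a tiny hand-written corpus.

Builds six abstracts, tags gene mentions with a dictionary lexicon
(including a conjunction pattern "IL-4 and -6"), counts document-level
co-occurrence with the disease phrase, and prints each gene's
hypergeometric tail p-value: the probability of seeing at least k joint
documents if the gene's m documents were placed at random among all N.
"""

from litnet import (
    Corpus,
    Document,
    Lexicon,
    LexiconEntry,
    count_gene_disease,
    score_all_genes,
    segment_sentences,
    tag_corpus,
)

lexicon = Lexicon(
    [
        LexiconEntry("7422", "VEGFA", ("VEGF-A",)),
        LexiconEntry("3569", "IL6", ("interleukin 6", "IL-6")),
        LexiconEntry("3565", "IL4", ()),
        LexiconEntry("7124", "TNF", ()),
    ]
)

texts = [
    ("d1", "VEGFA in bronchopulmonary dysplasia.", "VEGFA was elevated in cases."),
    ("d2", "Growth factors in preterm lung disease", "Infants with bronchopulmonary dysplasia showed high VEGF-A."),
    ("d3", "Cytokine profiles", "IL-4 and -6 rose after birth. No disease context here."),
    ("d4", "Inflammation in bronchopulmonary dysplasia", "Interleukin 6 correlated with severity."),
    ("d5", "Unrelated neonatal study", "TNF was unchanged in controls."),
    ("d6", "Another control cohort", "Nothing of note was measured."),
] + [
    (f"c{i}", "Control cohort record", "Routine follow-up with no gene assays.")
    for i in range(6)
]
corpus = Corpus([segment_sentences(Document(*t)) for t in texts])
mentions = tag_corpus(corpus, lexicon)
counts = count_gene_disease(corpus, mentions, ["bronchopulmonary dysplasia"])
results = score_all_genes(counts, alpha=0.05)

print(f"N={corpus.size} documents, n={results[0].counts.n} mention the disease\n")
print(f"{'gene':8s} {'m':>2s} {'k':>2s} {'p-value':>10s}  significant")
for r in results:
    print(
        f"{lexicon.symbol_of(r.gene_id):8s} {r.counts.m:2d} {r.counts.k:2d} "
        f"{r.p_value:10.4f}  {r.significant}"
    )
print(
    "\nA small p means the gene appears in disease documents far more often\n"
    "than random placement of its mentions would allow."
)
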