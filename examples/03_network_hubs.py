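"""Build a multi-evidence gene network and extract its hub genes.

Merges curated-style relation edges with sentence-level co-citation edges
mined from a toy corpus, then prints the degree histogram, the fitted
power-law exponent and the top hub genes.
"""

from litnet import (
    Corpus,
    Document,
    Evidence,
    Lexicon,
    LexiconEntry,
    cocitation_edges,
    degree_histogram,
    fit_power_law,
    identify_hubs,
    merge_network,
    relation_edge,
    segment_sentences,
    tag_corpus,
)

symbols = ["TP53", "AKT1", "JUN", "IL6", "INS", "BCL2", "VEGFA", "EGFR"]
lexicon = Lexicon([LexiconEntry(str(i), s) for i, s in enumerate(symbols)])

# curated relations: a hub (TP53) wired to everything, plus a few extras
curated = [
    relation_edge("0", str(i), "PPrel", [Evidence(source="ppi")]) for i in range(1, 8)
] + [
    relation_edge("1", "2", "GErel", [Evidence(source="kgml")]),
    relation_edge("3", "4", "ECrel", [Evidence(source="kgml")]),
]

# literature evidence: IL6 and VEGFA repeatedly co-cited in one sentence
docs = [
    segment_sentences(
        Document(str(d), "", "IL6 induced VEGFA in endothelium. Controls were stable.")
    )
    for d in range(4)
] + [
    segment_sentences(Document(f"bg{d}", "", "No gene content in this record."))
    for d in range(26)
]
corpus = Corpus(docs)
mentions = tag_corpus(corpus, lexicon)
cocit = cocitation_edges(corpus, mentions, alpha=0.05, min_support=2)

network = merge_network(curated, cocit)
print(f"network: {network.n_nodes} nodes, {network.n_edges} edges")
hist = degree_histogram(network)
print("degree histogram:", hist)
fit = fit_power_law(hist)
print(f"power-law fit: gamma={fit.exponent:.2f}, R^2={fit.goodness:.2f}")

hubs = identify_hubs(network, rule="top_k", param=2)
print("hubs:", [(lexicon.symbol_of(g), d) for g, d in hubs.genes])
print(
    "\nTP53 dominates because every evidence channel attaches to it; the\n"
    "IL6-VEGFA co-citation edge came from the corpus, not the curated files."
)
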