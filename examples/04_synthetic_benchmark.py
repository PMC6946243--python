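"""End-to-end benchmark on a synthetic corpus with planted ground truth.

Generates a corpus in which 8 planted genes are mentioned eight times more
often in disease documents, runs the full mining pipeline, and scores how
well the planted associations and the planted interaction graph were
recovered.
"""

import tempfile
from pathlib import Path

from litnet import GeneratorConfig, evaluate_recovery
from litnet.cooccurrence import count_gene_disease, score_all_genes
from litnet.ner import Lexicon, tag_corpus
from litnet.network import cocitation_edges, load_ppi_table, merge_network, parse_kgml
from litnet.synthetic import (
    DISEASE_TERMS,
    generate_corpus,
    generate_lexicon,
    generate_relation_files,
)

config = GeneratorConfig(seed=42, n_docs=1500, n_genes=150, n_planted=8)
entries = generate_lexicon(config)
corpus, truth = generate_corpus(config, entries)
lexicon = Lexicon(entries)

mentions = tag_corpus(corpus, lexicon)
counts = count_gene_disease(corpus, mentions, DISEASE_TERMS)
results = score_all_genes(counts, alpha=0.05)

with tempfile.TemporaryDirectory() as tmp:
    rel = generate_relation_files(config, Path(tmp))
    network = merge_network(
        parse_kgml(rel["kgml"]),
        load_ppi_table(rel["ppi"], valid_genes=lexicon.gene_ids),
        cocitation_edges(corpus, mentions, alpha=0.05),
    )

report = evaluate_recovery(results, truth, network=network)
print(f"corpus: N={truth.N} documents, n={truth.n} disease-positive")
print(f"planted genes: {report.n_planted}, predicted significant: {report.n_predicted}")
print(f"recall:    {report.recall:.2f}   (planted genes recovered)")
print(f"precision: {report.precision:.2f}   (predictions that are planted)")
print(f"FPR:       {report.fpr:.3f}  (should stay near the 0.05 test level)")
print(f"edge Jaccard vs planted graph: {report.edge_jaccard:.2f}")
print(
    "\nRecall near 1 shows the hypergeometric filter finds the planted signal;\n"
    "precision below 1 reflects true false positives at the raw .05 threshold."
)
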