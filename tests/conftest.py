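"""Shared fixtures: a small hand-built lexicon and a tiny synthetic dataset."""

from __future__ import annotations

import pytest

from litnet.corpus_io import Corpus, Document, segment_sentences
from litnet.ner import Lexicon, LexiconEntry
from litnet.synthetic import GeneratorConfig, generate_corpus, generate_lexicon


@pytest.fixture(scope="session")
def cytokine_lexicon() -> Lexicon:
    """Hand-built lexicon of well-known genes with aliases and traps."""
    return Lexicon(
        [
            LexiconEntry("3569", "IL6", ("interleukin 6", "IL-6")),
            LexiconEntry("3565", "IL4", ()),
            LexiconEntry("3558", "IL2", ()),
            LexiconEntry("7422", "VEGFA", ("VEGF-A",)),
            LexiconEntry("7423", "VEGFB", ()),
            LexiconEntry("4313", "MMP2", ()),
            LexiconEntry("4318", "MMP9", ()),
            LexiconEntry("7124", "TNF", ()),
            LexiconEntry("7132", "TNFRSF1A", ()),
            LexiconEntry("3630", "INS", ()),
        ]
    )


def make_doc(doc_id: str, title: str, abstract: str) -> Document:
    return segment_sentences(Document(doc_id, title, abstract))


@pytest.fixture(scope="session")
def tiny_config() -> GeneratorConfig:
    """Small but non-trivial study conditions for fast structural tests."""
    return GeneratorConfig(
        seed=7, n_docs=300, n_genes=60, n_planted=5, enrichment_factor=8.0
    )


@pytest.fixture(scope="session")
def tiny_dataset(tiny_config):
    entries = generate_lexicon(tiny_config)
    corpus, truth = generate_corpus(tiny_config, entries)
    return entries, corpus, truth
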