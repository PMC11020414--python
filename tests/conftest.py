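"""Shared fixtures: tiny vocabularies and corpora built programmatically."""

from __future__ import annotations

import numpy as np
import pytest

from meshsom.corpus import ArticleRecord, Vocabulary, VocabularyTerm, vectorize


def make_vocab(n: int, domain_frac: float = 0.2) -> Vocabulary:
    n_dom = int(n * domain_frac)
    terms = []
    for i in range(n):
        root = "F" if i < n_dom else "C"
        terms.append(
            VocabularyTerm(
                term_id=f"T{i:03d}",
                label=f"Term {i:03d}",
                tree_paths=(f"{root}01.{i:03d}",),
                is_domain=(i < n_dom),
            )
        )
    return Vocabulary(tuple(terms))


def random_corpus(vocab: Vocabulary, n: int, seed: int, max_terms: int = 9):
    rng = np.random.default_rng(seed)
    records = []
    for i in range(n):
        k = int(rng.integers(1, max_terms + 1))
        cols = rng.choice(vocab.D, size=k, replace=False)
        records.append(
            ArticleRecord(f"A{i:04d}", tuple(vocab.terms[c].term_id for c in cols))
        )
    return vectorize(records, vocab)


@pytest.fixture
def vocab20() -> Vocabulary:
    return make_vocab(20)


@pytest.fixture
def corpus_small(vocab20):
    return random_corpus(vocab20, 30, seed=7)
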