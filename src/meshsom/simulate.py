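"""Synthetic vocabularies, planted-topic corpora, and multi-edition citation sets.

The generator emulates the statistical shape of an annotated literature
corpus: a hierarchical controlled vocabulary with a designated domain
(psychiatric) subtree, articles annotated with on average 9 terms drawn from
planted topic signatures plus uniform background, and successive "editions"
of citation lists with a controlled persistence rate.  Ground truth (topic
labels, planted rates, seeds) is recorded so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .corpus import AnnotatedCorpus, ArticleRecord, Vocabulary, VocabularyTerm, vectorize

__all__ = [
    "TopicSpec",
    "SyntheticTruth",
    "make_vocabulary",
    "make_topics",
    "make_corpus",
    "make_editions",
    "DEFAULT_MEAN_ANNOTATIONS",
]

# articles in the emulated corpus carry ~9 annotations on average
DEFAULT_MEAN_ANNOTATIONS = 9.0

DOMAIN_PREFIX = "F"  # synthetic stand-in for the psychiatric subtree root


@dataclass(frozen=True)
class TopicSpec:
    """A planted topic: a term signature plus the probability that a drawn
    annotation comes from the signature rather than uniform background."""

    topic_id: str
    signature_terms: tuple[str, ...]
    signature_prob: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.signature_prob <= 1.0):
            raise ValueError("signature_prob must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Everything needed to score recovery of the planted structure."""

    seed: int
    topic_of: dict[str, str] = field(default_factory=dict)  # article_id -> topic_id
    planted_persistence: float | None = None
    params: dict = field(default_factory=dict)

    def topic_labels(self, article_ids: Sequence[str]) -> np.ndarray:
        topics = sorted(set(self.topic_of.values()))
        code = {t: i for i, t in enumerate(topics)}
        return np.array([code[self.topic_of[a]] for a in article_ids])

    def to_json(self, path: str | Path) -> None:
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(
                {
                    "seed": self.seed,
                    "topic_of": self.topic_of,
                    "planted_persistence": self.planted_persistence,
                    "params": self.params,
                },
                fh, indent=1, sort_keys=True,
            )


def make_vocabulary(
    n_terms: int, n_domain: int, seed: int = 0, domain_prefix: str = DOMAIN_PREFIX
) -> Vocabulary:
    """A synthetic controlled vocabulary with dot-numbered tree paths.

    Exactly ``n_domain`` terms sit under ``domain_prefix``; the rest are
    spread over eight other top-level branches.  Deterministic per seed.
    """
    if n_domain > n_terms:
        raise ValueError("n_domain cannot exceed n_terms")
    rng = np.random.default_rng(seed)
    branches = [b for b in "ABCDEGHIJ" if not b.startswith(domain_prefix)][:8]
    terms = []
    width = len(str(n_terms))
    for i in range(n_terms):
        term_id = f"T{i:0{width}d}"
        if i < n_domain:
            root = domain_prefix
        else:
            root = branches[int(rng.integers(0, len(branches)))]
        depth = int(rng.integers(1, 4))
        path = root + "01" + "".join(
            f".{int(rng.integers(100, 999))}" for _ in range(depth)
        )
        terms.append(
            VocabularyTerm(
                term_id=term_id,
                label=f"Term {i}",
                tree_paths=(path,),
                is_domain=(i < n_domain),
            )
        )
    return Vocabulary(tuple(terms))


def make_topics(
    vocab: Vocabulary,
    n_topics: int,
    signature_size: int = 10,
    signature_prob: float = 0.9,
    domain_only: bool = False,
) -> tuple[TopicSpec, ...]:
    """Pairwise-disjoint topic signatures spread evenly over the vocabulary.

    Signatures are taken at evenly spaced positions and dealt round-robin to
    topics, so each topic mixes domain and non-domain terms (unless
    ``domain_only`` restricts the pool to the domain subtree).
    """
    pool = [t.term_id for t in vocab.terms if (t.is_domain or not domain_only)]
    need = n_topics * signature_size
    if need > len(pool):
        raise ValueError("vocabulary too small for the requested signatures")
    flat = np.linspace(0, len(pool) - 1, need).astype(int)
    if len(set(flat)) < need:  # tiny pools: fall back to the front block
        flat = np.arange(need)
    return tuple(
        TopicSpec(
            topic_id=f"topic{g}",
            signature_terms=tuple(pool[i] for i in flat[g::n_topics]),
            signature_prob=signature_prob,
        )
        for g in range(n_topics)
    )


def make_corpus(
    vocab: Vocabulary,
    topics: Sequence[TopicSpec],
    n_articles: int,
    mean_annotations: float = DEFAULT_MEAN_ANNOTATIONS,
    seed: int = 0,
) -> tuple[AnnotatedCorpus, SyntheticTruth]:
    """Planted-topic corpus: per article a uniform topic, a Poisson-(>=1)
    annotation count, and each annotation drawn from the topic signature with
    probability ``signature_prob`` else uniformly from the whole vocabulary."""
    if mean_annotations < 1:
        raise ValueError("mean_annotations must be >= 1")
    if not topics:
        raise ValueError("need at least one topic")
    rng = np.random.default_rng(seed)
    all_terms = [t.term_id for t in vocab.terms]
    records = []
    topic_of: dict[str, str] = {}
    width = len(str(max(n_articles - 1, 1)))
    for i in range(n_articles):
        article_id = f"A{i:0{width}d}"
        topic = topics[int(rng.integers(0, len(topics)))]
        n_ann = 0
        while n_ann < 1:
            n_ann = int(rng.poisson(mean_annotations))
        n_ann = min(n_ann, len(all_terms))
        # draw until n_ann DISTINCT terms: the annotation count of a record is
        # a set size, so duplicates are redrawn rather than silently dropped
        chosen: dict[str, None] = {}
        attempts = 0
        while len(chosen) < n_ann and attempts < 100 * n_ann:
            attempts += 1
            if rng.random() < topic.signature_prob:
                t = topic.signature_terms[
                    int(rng.integers(0, len(topic.signature_terms)))
                ]
            else:
                t = all_terms[int(rng.integers(0, len(all_terms)))]
            chosen.setdefault(t, None)
        records.append(ArticleRecord(article_id, tuple(chosen)))
        topic_of[article_id] = topic.topic_id
    corpus = vectorize(records, vocab, strict=True)
    truth = SyntheticTruth(
        seed=seed,
        topic_of=topic_of,
        params=dict(
            n_articles=n_articles,
            mean_annotations=mean_annotations,
            n_topics=len(topics),
            signature_prob=topics[0].signature_prob,
        ),
    )
    return corpus, truth


def make_editions(
    article_ids: Sequence[str],
    n_editions: int,
    sizes: Sequence[int] | int,
    persistence_rate: float,
    seed: int = 0,
) -> tuple[list[list[str]], SyntheticTruth]:
    """Successive edition citation lists with a planted persistence rate.

    Edition 1 is sampled uniformly without replacement; edition e keeps each
    id of edition e-1 independently with probability ``persistence_rate`` and
    fills to its size with fresh ids drawn from the corpus excluding the
    previous edition, so the measured consecutive-edition persistence is
    exactly Binomial(size, rate) / size (no chance-overlap inflation).
    """
    if not (0.0 <= persistence_rate <= 1.0):
        raise ValueError("persistence_rate must be in [0, 1]")
    if isinstance(sizes, int):
        sizes = [sizes] * n_editions
    if len(sizes) != n_editions:
        raise ValueError("sizes must have one entry per edition")
    ids = list(article_ids)
    if max(sizes) > len(ids):
        raise ValueError("requested edition size exceeds corpus size")
    rng = np.random.default_rng(seed)
    editions: list[list[str]] = []
    prev: list[str] = []
    for e, size in enumerate(sizes):
        if e == 0:
            chosen = list(rng.choice(ids, size=size, replace=False))
        else:
            keep_mask = rng.random(len(prev)) < persistence_rate
            kept = [a for a, k in zip(prev, keep_mask) if k][:size]
            excluded = set(prev) | set(kept)
            pool = [a for a in ids if a not in excluded]
            n_fill = size - len(kept)
            fill = list(rng.choice(pool, size=n_fill, replace=False))
            chosen = kept + fill
        editions.append(chosen)
        prev = chosen
    truth = SyntheticTruth(
        seed=seed,
        planted_persistence=persistence_rate,
        params=dict(n_editions=n_editions, sizes=list(sizes)),
    )
    return editions, truth
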