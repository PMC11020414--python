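"""End-to-end recovery studies on synthetic corpora with known ground truth.

Two self-contained experiments exercise the full pipeline:

* :func:`topic_recovery` — plant G disjoint topics, train a small map, project
  the corpus, cluster the grid positions, and score the recovered partition
  against the planted labels (adjusted Rand index) plus the elbow-selected
  cluster count.
* :func:`persistence_recovery` — plant a citation-persistence rate across
  synthetic editions and compare the measured consecutive-edition persistence
  with the planted rate on the binomial standard-error scale.

These are the package's own validation conditions; the defaults here are the
study conditions, not tuning knobs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .projection import kmeans_grid, project, wss_curve
from .simulate import make_corpus, make_editions, make_topics, make_vocabulary
from .som import GridGeometry, TrainingSchedule, train

__all__ = ["TopicRecoveryResult", "PersistenceRecoveryResult",
           "topic_recovery", "persistence_recovery"]


@dataclass(frozen=True)
class TopicRecoveryResult:
    ari: float
    elbow_k: int
    n_articles: int
    n_topics: int
    te_min: float
    epoch_of_origin: int


def topic_recovery(
    seed: int,
    n_topics: int = 4,
    n_articles: int = 2000,
    n_terms: int = 200,
    n_domain: int = 40,
    signature_prob: float = 0.9,
    rows: int = 20,
    cols: int = 20,
    epochs: int = 20,
    sigma0: float = 9.0,
    decay_base: float = 1.7,
    train_restarts: int = 5,
    kmeans_restarts: int = 10,
    k_max: int = 12,
) -> TopicRecoveryResult:
    """Planted-topic recovery through the full train/project/cluster pipeline.

    The map is trained with the blended principal-plane + sampled-article
    initialization and the lowest topographic error over ``train_restarts``
    restarts x ``epochs`` epochs selects the codebook — on grids this small
    pure article-sampling is prone to topological folds, and the fold shows
    up as exactly the error this selection minimizes.  sigma0 defaults to
    just under half the grid side, the same fraction-of-grid convention as
    the full-scale schedule.
    """
    vocab = make_vocabulary(n_terms, n_domain, seed=seed)
    topics = make_topics(vocab, n_topics, signature_prob=signature_prob)
    corpus, truth = make_corpus(vocab, topics, n_articles, seed=seed)
    schedule = TrainingSchedule(
        epochs=epochs, sigma0=sigma0, decay_base=decay_base, rng_seed=seed
    )
    codebook = train(
        corpus, GridGeometry(rows, cols), schedule,
        init="pca_sample", restarts=train_restarts,
    )
    proj = project(corpus, codebook)
    pts = proj.points()
    _, labels, _ = kmeans_grid(pts, n_topics, restarts=kmeans_restarts, seed=seed)
    ari = adjusted_rand_score(truth.topic_labels(proj.article_ids), labels)
    curve = wss_curve(pts, k_max=k_max, restarts=kmeans_restarts, seed=seed)
    return TopicRecoveryResult(
        ari=float(ari),
        elbow_k=curve.chosen_k,
        n_articles=corpus.N,
        n_topics=n_topics,
        te_min=float(min(codebook.te_history)),
        epoch_of_origin=codebook.epoch_of_origin,
    )


@dataclass(frozen=True)
class PersistenceRecoveryResult:
    planted_rate: float
    measured_mean_pct: float
    planted_pct: float
    abs_error_pct: float
    se_pct: float
    n_transitions: int
    edition_size: int

    @property
    def within_3se(self) -> bool:
        return self.abs_error_pct <= 3.0 * self.se_pct


def persistence_recovery(
    seed: int,
    corpus_size: int = 50_000,
    n_editions: int = 10,
    edition_size: int = 4000,
    rate: float = 0.26,
) -> PersistenceRecoveryResult:
    """Measure consecutive-edition citation persistence on planted editions.

    Each transition keeps every id with probability ``rate``, so the measured
    per-transition persistence is Binomial(edition_size, rate)/edition_size;
    the mean over the n-1 transitions is compared with the planted rate and
    reported with the standard error of that mean.
    """
    ids = [f"A{i}" for i in range(corpus_size)]
    editions, _ = make_editions(ids, n_editions, edition_size, rate, seed=seed)
    fracs = []
    for prev, curr in zip(editions, editions[1:]):
        pset = set(prev)
        fracs.append(sum(1 for a in curr if a in pset) / len(curr))
    measured = 100.0 * float(np.mean(fracs))
    n_tr = len(fracs)
    se = 100.0 * float(
        np.sqrt(rate * (1.0 - rate) / (edition_size * n_tr))
    )
    return PersistenceRecoveryResult(
        planted_rate=rate,
        measured_mean_pct=measured,
        planted_pct=100.0 * rate,
        abs_error_pct=abs(measured - 100.0 * rate),
        se_pct=se,
        n_transitions=n_tr,
        edition_size=edition_size,
    )
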