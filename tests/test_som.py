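"""Batch SOM: BMU search, batch epochs, topographic error, training, I/O."""

from __future__ import annotations

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

from meshsom.corpus import AnnotatedCorpus, vectorize
from meshsom.som import (
    Codebook,
    GridGeometry,
    TrainingSchedule,
    batch_epoch,
    classify_nodes,
    export_weights_tsv,
    find_bmu,
    find_bmus,
    init_codebook,
    load_codebook,
    save_codebook,
    topographic_error,
    train,
)
from meshsom.simulate import make_corpus, make_topics, make_vocabulary
from .conftest import make_vocab, random_corpus


def toy_codebook(W: np.ndarray, rows: int, cols: int, **kw) -> Codebook:
    return Codebook(geometry=GridGeometry(rows, cols), W=np.asarray(W, float), **kw)


def corpus_from_rows(rows: np.ndarray, vocab=None) -> AnnotatedCorpus:
    """Binary matrix rows -> corpus with synthetic ids (bypasses term names)."""
    rows = np.asarray(rows)
    vocab = vocab or make_vocab(rows.shape[1])
    recs = [
        (f"A{i}", tuple(vocab.terms[j].term_id for j in np.flatnonzero(r)))
        for i, r in enumerate(rows)
    ]
    return vectorize(recs, vocab)


class TestGridGeometry:
    def test_node_indexing_row_major(self):
        g = GridGeometry(3, 4)
        assert g.M == 12
        assert g.to_coord(7) == (1, 3)
        coords = g.coords()
        assert coords.shape == (12, 2)
        assert tuple(coords[7]) == (1.0, 3.0)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(ValueError):
            GridGeometry(0, 5)


class TestTrainingSchedule:
    def test_sigma_strictly_decreasing_and_positive(self):
        s = TrainingSchedule(epochs=20, sigma0=175.0, decay_base=1.7)
        sigmas = [s.sigma(e) for e in range(1, 21)]
        assert all(a > b > 0 for a, b in zip(sigmas, sigmas[1:]))
        assert sigmas[0] == pytest.approx(175.0 / 1.7)
        assert sigmas[19] == pytest.approx(175.0 / 1.7**20)

    def test_neighborhood_shrinks_below_one_grid_unit_when_computed(self):
        # the crossing epoch is computed from the schedule, not hard-coded
        s = TrainingSchedule(epochs=20, sigma0=175.0, decay_base=1.7)
        e = s.unit_crossing_epoch()
        assert s.sigma(e) < 1.0 <= s.sigma(e - 1)
        assert e <= 12

    def test_invalid_parameters_rejected(self):
        for kw in (dict(sigma0=0.0), dict(decay_base=1.0), dict(epochs=0),
                   dict(kernel="triangle")):
            with pytest.raises(ValueError):
                TrainingSchedule(**kw)


class TestInitCodebook:
    def test_same_seed_gives_identical_codebooks(self, corpus_small):
        s = TrainingSchedule(rng_seed=42)
        g = GridGeometry(4, 4)
        cb1 = init_codebook(corpus_small, g, s)
        cb2 = init_codebook(corpus_small, g, s)
        assert np.array_equal(cb1.W, cb2.W)

    def test_single_article_no_jitter_copies_it_everywhere(self, vocab20):
        corpus = vectorize([("A1", ("T001", "T005"))], vocab20)
        cb = init_codebook(corpus, GridGeometry(3, 3), TrainingSchedule(), jitter=0.0)
        expected = np.asarray(corpus.matrix.todense())[0]
        assert np.array_equal(cb.W, np.tile(expected, (9, 1)))

    def test_sampled_indices_match_independent_prng_trace(self, vocab20):
        corpus = random_corpus(vocab20, 100, seed=3)
        seed = 11
        cb = init_codebook(
            corpus, GridGeometry(5, 5), TrainingSchedule(rng_seed=seed), jitter=0.0
        )
        expected_picks = np.random.default_rng(seed).integers(0, 100, size=25)
        expected = np.asarray(corpus.matrix[expected_picks].todense())
        assert np.array_equal(cb.W, expected)

    def test_empty_corpus_rejected(self, vocab20):
        empty = vectorize([], vocab20)
        with pytest.raises(ValueError):
            init_codebook(empty, GridGeometry(3, 3), TrainingSchedule())

    def test_blended_init_stays_in_unit_interval(self, corpus_small):
        cb = init_codebook(
            corpus_small, GridGeometry(5, 5), TrainingSchedule(rng_seed=1),
            method="pca_sample",
        )
        assert cb.W.min() >= 0.0 and cb.W.max() <= 1.0


class TestFindBmu:
    def test_exact_weight_match_is_first_bmu_with_zero_distance(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(size=(9, 6)).round(2)
        x = np.zeros(6)
        x[:3] = 1.0
        W[5] = x
        pair = find_bmu(x, toy_codebook(W, 3, 3))
        assert pair.first == 5
        assert pair.first_dist2 == pytest.approx(0.0, abs=1e-9)

    def test_two_by_two_toy_matches_dense_scan(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0], [0.0, 0.0]])
        x = np.array([1.0, 1.0])
        pair = find_bmu(x, toy_codebook(W, 2, 2))
        dense = np.argsort(((W - x) ** 2).sum(axis=1), kind="stable")
        assert (pair.first, pair.second) == (dense[0], dense[1]) == (2, 0)

    def test_all_identical_nodes_tie_break_by_index(self):
        W = np.ones((6, 4)) * 0.5
        pair = find_bmu(np.ones(4), toy_codebook(W, 2, 3))
        assert (pair.first, pair.second) == (0, 1)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError, match="dimension"):
            find_bmu(np.ones(3), toy_codebook(np.ones((4, 5)), 2, 2))

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(seed=st.integers(0, 10_000))
    def test_sparse_search_equals_dense_bruteforce(self, seed):
        """Sparse-expansion BMU search == dense argmin, including tie cases."""
        rng = np.random.default_rng(seed)
        M = int(rng.integers(2, 50))
        D = int(rng.integers(2, 30))
        n = int(rng.integers(1, 20))
        # quantized weights provoke ties
        W = rng.integers(0, 3, size=(M, D)).astype(float) / 2.0
        rows = 1
        while rows * rows < M:
            rows += 1
        cb = Codebook(geometry=GridGeometry(rows, int(np.ceil(M / rows))), W=np.vstack(
            [W, np.full((rows * int(np.ceil(M / rows)) - M, D), 1e6)]))
        X = sp.csr_matrix((rng.random((n, D)) < 0.3).astype(float))
        b1, b2, d1, d2 = find_bmus(X, cb)
        Xd = np.asarray(X.todense())
        for i in range(n):
            dist2 = ((cb.W - Xd[i]) ** 2).sum(axis=1)
            order = np.argsort(dist2, kind="stable")
            assert b1[i] == order[0]
            assert b2[i] == order[1]
            assert d1[i] == pytest.approx(dist2[order[0]], abs=1e-8)
            assert d1[i] <= d2[i] + 1e-12


class TestBatchEpoch:
    def test_huge_sigma_pulls_every_node_to_single_article(self, vocab20):
        corpus = vectorize([("A1", ("T001", "T004"))], vocab20)
        cb = init_codebook(corpus, GridGeometry(3, 3), TrainingSchedule(rng_seed=0))
        out = batch_epoch(cb, corpus, sigma_e=1e6)
        target = np.asarray(corpus.matrix.todense())[0]
        assert np.allclose(out.W, np.tile(target, (9, 1)), atol=1e-9)

    def test_tiny_sigma_moves_only_bmu_nodes(self):
        # nodes on a 1x3 grid; two articles each exactly matching one node
        W = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        corpus = corpus_from_rows(np.array([[1, 0, 0], [0, 0, 1]]))
        cb = toy_codebook(W, 1, 3)
        out = batch_epoch(cb, corpus, sigma_e=1e-3)
        assert np.allclose(out.W[0], [1, 0, 0])
        assert np.allclose(out.W[2], [0, 0, 1])
        assert np.allclose(out.W[1], W[1])  # no mass: frozen

    def test_hand_computed_weighted_mean_three_nodes_two_articles(self):
        # 1x3 grid, articles x1=(1,0), x2=(0,1); BMUs: node0, node2
        W = np.array([[0.9, 0.1], [0.5, 0.5], [0.1, 0.9]])
        corpus = corpus_from_rows(np.array([[1, 0], [0, 1]]))
        sigma = 1.0
        h = lambda d2: np.exp(-d2 / (2 * sigma**2))
        # node0: h(0)*x1 + h(4)*x2 ; node1: h(1)*(x1+x2) ; node2: h(4)*x1 + h(0)*x2
        expected = np.array(
            [
                (h(0) * np.array([1, 0]) + h(4) * np.array([0, 1])) / (h(0) + h(4)),
                (h(1) * np.array([1, 0]) + h(1) * np.array([0, 1])) / (2 * h(1)),
                (h(4) * np.array([1, 0]) + h(0) * np.array([0, 1])) / (h(0) + h(4)),
            ]
        )
        out = batch_epoch(toy_codebook(W, 1, 3), corpus, sigma_e=sigma)
        assert np.allclose(out.W, expected, atol=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(seed=st.integers(0, 1000), sigma=st.floats(0.1, 20.0))
    def test_weights_remain_in_unit_interval(self, seed, sigma):
        """Batch updates are convex combinations of binary inputs."""
        vocab = make_vocab(15)
        corpus = random_corpus(vocab, 25, seed=seed)
        cb = init_codebook(corpus, GridGeometry(4, 4),
                           TrainingSchedule(rng_seed=seed))
        out = batch_epoch(cb, corpus, sigma_e=sigma)
        assert out.W.min() >= 0.0 and out.W.max() <= 1.0

    def test_article_order_invariance_is_bitwise(self, vocab20):
        corpus = random_corpus(vocab20, 40, seed=5)
        perm = np.random.default_rng(0).permutation(40)
        shuffled = corpus.subset(perm)
        cb = init_codebook(corpus, GridGeometry(4, 4), TrainingSchedule(rng_seed=9))
        out1 = batch_epoch(cb, corpus, sigma_e=2.0)
        out2 = batch_epoch(cb, shuffled, sigma_e=2.0)
        assert np.array_equal(out1.W, out2.W)

    def test_nonpositive_sigma_rejected(self, corpus_small):
        cb = init_codebook(corpus_small, GridGeometry(3, 3), TrainingSchedule())
        with pytest.raises(ValueError):
            batch_epoch(cb, corpus_small, sigma_e=0.0)


class TestTopographicError:
    def test_adjacent_bmus_give_zero(self):
        # article matches node 0 exactly; runner-up is its neighbor node 1
        W = np.array([[1.0, 0.0], [0.9, 0.0], [0.0, 1.0], [0.0, 0.9]])
        corpus = corpus_from_rows(np.array([[1, 0]]))
        assert topographic_error(toy_codebook(W, 2, 2), corpus) == 0.0

    def test_opposite_corner_bmus_give_one(self):
        # best node 0 (corner), second-best node 8 (opposite corner) on 3x3
        W = np.full((9, 2), 5.0)
        W[0] = [1.0, 0.0]
        W[8] = [0.9, 0.0]
        corpus = corpus_from_rows(np.array([[1, 0]]))
        assert topographic_error(toy_codebook(W, 3, 3), corpus) == 1.0

    def test_mixed_corpus_matches_bruteforce_recount(self):
        rng = np.random.default_rng(12)
        W = rng.integers(0, 2, size=(16, 10)).astype(float)
        cb = toy_codebook(W, 4, 4)
        corpus = corpus_from_rows((rng.random((10, 10)) < 0.4).astype(int))
        te = topographic_error(cb, corpus)
        b1, b2, _, _ = find_bmus(corpus.matrix, cb)
        errors = 0
        for i in range(10):
            r1, c1 = divmod(int(b1[i]), 4)
            r2, c2 = divmod(int(b2[i]), 4)
            if max(abs(r1 - r2), abs(c1 - c2)) != 1:
                errors += 1
        assert te == pytest.approx(errors / 10)

    def test_value_always_in_unit_interval(self, corpus_small):
        cb = init_codebook(corpus_small, GridGeometry(5, 5),
                           TrainingSchedule(rng_seed=2))
        assert 0.0 <= topographic_error(cb, corpus_small) <= 1.0


class TestTrain:
    def test_single_epoch_returns_that_state(self, corpus_small):
        sched = TrainingSchedule(epochs=1, sigma0=3.0, rng_seed=4)
        g = GridGeometry(4, 4)
        cb = train(corpus_small, g, sched)
        manual = batch_epoch(
            init_codebook(corpus_small, g, sched), corpus_small, sched.sigma(1)
        )
        assert np.array_equal(cb.W, manual.W)
        assert cb.epoch_of_origin == 1
        assert len(cb.te_history) == 1

    def test_fixed_seed_training_is_bit_reproducible(self, corpus_small):
        sched = TrainingSchedule(epochs=3, sigma0=3.0, rng_seed=21)
        g = GridGeometry(4, 4)
        cb1 = train(corpus_small, g, sched)
        cb2 = train(corpus_small, g, sched)
        assert np.array_equal(cb1.W, cb2.W)
        assert cb1.te_history == cb2.te_history

    def test_selected_codebook_has_minimal_te(self, corpus_small):
        sched = TrainingSchedule(epochs=5, sigma0=4.0, rng_seed=1)
        cb = train(corpus_small, GridGeometry(5, 5), sched)
        assert min(cb.te_history) == cb.te_history[cb.epoch_of_origin - 1]

    def test_planted_topics_separate_on_the_grid(self):
        """Mean within-topic BMU distance < mean between-topic distance."""
        vocab = make_vocabulary(100, 20, seed=0)
        topics = make_topics(vocab, 4, signature_size=8, signature_prob=0.9)
        corpus, truth = make_corpus(vocab, topics, 400, seed=0)
        sched = TrainingSchedule(epochs=10, sigma0=4.0, rng_seed=0)
        cb = train(corpus, GridGeometry(10, 10), sched, init="pca_sample")
        b1, _, _, _ = find_bmus(corpus.matrix, cb)
        coords = cb.geometry.coords()[b1]
        labels = truth.topic_labels(corpus.article_ids)
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        same = labels[:, None] == labels[None, :]
        off = ~np.eye(len(labels), dtype=bool)
        assert d[same & off].mean() < d[~same].mean()


class TestClassifyNodes:
    def test_pure_domain_node_is_positive(self, vocab20):
        W = np.zeros((4, 20))
        W[0, 0] = 1.0  # column 0 is a domain term in make_vocab
        labels = classify_nodes(toy_codebook(W, 2, 2), vocab20)
        assert labels[0]
        assert not labels[1]

    def test_uniform_weights_are_negative(self, vocab20):
        W = np.full((4, 20), 0.5)
        assert not classify_nodes(toy_codebook(W, 2, 2), vocab20).any()

    def test_random_nodes_match_hand_mean_comparison(self, vocab20):
        rng = np.random.default_rng(8)
        W = rng.uniform(size=(5, 20))
        cb = Codebook(geometry=GridGeometry(1, 5), W=W)
        mask = vocab20.domain_mask
        expected = W[:, mask].mean(axis=1) > W[:, ~mask].mean(axis=1)
        assert np.array_equal(classify_nodes(cb, vocab20), expected)

    def test_no_domain_terms_is_an_error(self):
        vocab = make_vocab(10, domain_frac=0.0)
        with pytest.raises(ValueError, match="domain"):
            classify_nodes(toy_codebook(np.ones((4, 10)), 2, 2), vocab)


class TestCodebookIO:
    def test_save_load_roundtrip_is_bitwise(self, tmp_path, corpus_small):
        sched = TrainingSchedule(epochs=2, sigma0=3.0, rng_seed=13)
        cb = train(corpus_small, GridGeometry(3, 3), sched)
        p = tmp_path / "cb.h5"
        save_codebook(cb, p)
        back = load_codebook(p)
        assert np.array_equal(back.W, cb.W)
        assert back.te_history == cb.te_history
        assert back.schedule == cb.schedule
        assert back.geometry == cb.geometry

    def test_tsv_export_has_one_row_per_node(self, tmp_path):
        cb = toy_codebook(np.random.default_rng(0).uniform(size=(6, 3)), 2, 3)
        p = tmp_path / "w.tsv"
        export_weights_tsv(cb, p)
        lines = p.read_text().splitlines()
        assert len(lines) == 1 + 6

    def test_corrupted_file_is_a_format_error(self, tmp_path):
        p = tmp_path / "junk.h5"
        p.write_bytes(b"this is not hdf5")
        with pytest.raises(ValueError, match="codebook"):
            load_codebook(p)

    def test_digest_mismatch_warns(self, tmp_path, corpus_small, caplog):
        sched = TrainingSchedule(epochs=1, sigma0=2.0, rng_seed=0)
        cb = train(corpus_small, GridGeometry(3, 3), sched)
        p = tmp_path / "cb.h5"
        save_codebook(cb, p)
        other_vocab = make_vocab(21)  # different column layout, different digest
        with caplog.at_level("WARNING"):
            load_codebook(p, vocab=other_vocab)
        assert "digest" in caplog.text
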