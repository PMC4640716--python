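"""Skip-gram negative-sampling training and its oracles."""

import math

import numpy as np
import pytest

from protembed.corpus import Corpus, NGramSentence
from protembed.embedding import (EmbeddingModel, TrainingConfig, TrainingPair,
                                 Vocabulary, build_vocabulary, cosine_similarity,
                                 generate_pairs, initialize_model, load_model,
                                 nearest_neighbors, noise_distribution,
                                 pair_probability, sample_noise_tokens,
                                 save_model, sgns_gradients, sgns_objective,
                                 train)
from protembed.synthetic import cooccurrence_toy_corpus


def _corpus_of(*sentences):
    return Corpus([NGramSentence(list(s), f"s{i}", 0)
                   for i, s in enumerate(sentences)], n=3)


class TestVocabulary:
    def test_min_count_threshold(self):
        c = _corpus_of(["MAK", "MAK", "AKQ"], ["MAK"])
        assert build_vocabulary(c, min_count=2).tokens == ["MAK"]
        assert build_vocabulary(c, min_count=1).tokens == ["MAK", "AKQ"]

    def test_ordering_count_then_lex(self):
        c = _corpus_of(["BBB", "AAA", "CCC", "AAA", "BBB"])
        assert build_vocabulary(c).tokens == ["AAA", "BBB", "CCC"]

    def test_exhaustive_three_grams(self):
        alpha = "ACDEFGHIKLMNPQRSTVWY"
        tokens = [a + b + c for a in alpha for b in alpha for c in alpha]
        c = _corpus_of(tokens)
        assert len(build_vocabulary(c)) == 8000

    def test_empty_corpus_raises(self):
        with pytest.raises(ValueError):
            build_vocabulary(Corpus([], n=3))

    def test_overfiltering_raises(self):
        with pytest.raises(ValueError):
            build_vocabulary(_corpus_of(["MAK"]), min_count=5)


class TestGeneratePairs:
    def setup_method(self):
        self.vocab = Vocabulary(tokens=["a", "b", "d"],
                                counts={"a": 1, "b": 1, "d": 1})

    def pairs(self, tokens, c):
        return [(p.center, p.context) for p in
                generate_pairs(NGramSentence(tokens, "s", 0), c, self.vocab)]

    def test_wide_window_all_ordered_pairs(self):
        i = self.vocab.index
        assert self.pairs(["a", "b", "d"], 25) == [
            (i["a"], i["b"]), (i["a"], i["d"]), (i["b"], i["a"]),
            (i["b"], i["d"]), (i["d"], i["a"]), (i["d"], i["b"])]

    def test_window_one(self):
        assert len(self.pairs(["a", "b", "d"], 1)) == 4

    def test_empty_sentence(self):
        assert self.pairs([], 25) == []

    def test_oov_skipped_but_occupies_position(self):
        # "x" is out of vocabulary: no pair includes it, but it separates
        # "a" and "d" beyond a window of 1
        assert self.pairs(["a", "x", "d"], 1) == []
        assert len(self.pairs(["a", "x", "d"], 2)) == 2


class TestNoiseDistribution:
    def test_single_token(self):
        v = Vocabulary(tokens=["a"], counts={"a": 7})
        assert noise_distribution(v).tolist() == [1.0]

    def test_symmetric_counts(self):
        v = Vocabulary(tokens=["a", "b"], counts={"a": 1, "b": 1})
        np.testing.assert_allclose(noise_distribution(v, 0.75), [0.5, 0.5])

    def test_power_law(self):
        # 16^0.75 = 8, so probabilities are 8/9 and 1/9
        v = Vocabulary(tokens=["a", "b"], counts={"a": 16, "b": 1})
        np.testing.assert_allclose(noise_distribution(v, 0.75), [8 / 9, 1 / 9])

    def test_sums_to_one(self):
        rng = np.random.default_rng(0)
        counts = {f"t{i}": int(c) for i, c in
                  enumerate(rng.integers(1, 1000, size=50))}
        v = Vocabulary(tokens=list(counts), counts=counts)
        assert abs(noise_distribution(v).sum() - 1.0) < 1e-12

    def test_empirical_sampling_matches_distribution(self):
        """1e5 inverse-CDF draws match the law within 3 standard errors."""
        counts = {"a": 160, "b": 40, "c": 10, "d": 1}
        v = Vocabulary(tokens=list(counts), counts=counts)
        probs = noise_distribution(v)
        n = 100_000
        draws = sample_noise_tokens(probs, n, seed=5)
        freqs = np.bincount(draws, minlength=4) / n
        se = np.sqrt(probs * (1 - probs) / n)
        assert (np.abs(freqs - probs) <= 3 * se).all()


class TestPairProbability:
    def test_zero_vectors_give_half(self, random_model):
        m = random_model
        m.input_vectors[0] = 0.0
        assert pair_probability(m, m.vocab.tokens[0], m.vocab.tokens[1]) == 0.5

    def test_log3_dot_product(self):
        # sigmoid(ln 3) = 3/4
        vocab = Vocabulary(tokens=["w", "c"], counts={"w": 1, "c": 1})
        inp = np.array([[math.log(3.0)], [0.0]])
        out = np.array([[0.0], [1.0]])
        m = EmbeddingModel(vocab=vocab, dim=1, input_vectors=inp, output_vectors=out)
        assert abs(pair_probability(m, "w", "c") - 0.75) < 1e-12

    def test_oov_raises(self, random_model):
        with pytest.raises(KeyError):
            pair_probability(random_model, "nope", random_model.vocab.tokens[0])


class TestObjectiveAndGradients:
    def test_zero_model_objective(self, random_model):
        m = random_model
        m.input_vectors[:] = 0.0
        m.output_vectors[:] = 0.0
        pos = [TrainingPair(0, 1)]
        neg = [TrainingPair(0, 2, "negative")]
        assert abs(sgns_objective(m, pos, neg) - 2 * math.log(0.5)) < 1e-12

    def test_empty_pairs_zero(self, random_model):
        assert sgns_objective(random_model, [], []) == 0.0

    def test_gradient_matches_finite_differences(self):
        """Analytic SGNS gradients vs central differences, 100 instances.

        Fourth-order central differences with h = 1e-4 keep the
        truncation and roundoff of the numerical oracle itself well below
        the 1e-6 relative tolerance being asserted.
        """
        rng = np.random.default_rng(11)
        h = 1e-4
        for _ in range(100):
            W, d = 5, 3
            tokens = [f"t{i}" for i in range(W)]
            vocab = Vocabulary(tokens=tokens, counts={t: 1 for t in tokens})
            model = EmbeddingModel(
                vocab=vocab, dim=d,
                input_vectors=rng.normal(scale=0.8, size=(W, d)),
                output_vectors=rng.normal(scale=0.8, size=(W, d)))
            pos = [TrainingPair(int(rng.integers(W)), int(rng.integers(W)))
                   for _ in range(4)]
            neg = [TrainingPair(int(rng.integers(W)), int(rng.integers(W)), "negative")
                   for _ in range(4)]
            g_in, g_out = sgns_gradients(model, pos, neg)
            for table, grad in ((model.input_vectors, g_in),
                                (model.output_vectors, g_out)):
                for i in range(W):
                    for k in range(d):
                        orig = table[i, k]
                        vals = []
                        for step in (-2 * h, -h, h, 2 * h):
                            table[i, k] = orig + step
                            vals.append(sgns_objective(model, pos, neg))
                        table[i, k] = orig
                        fd = (vals[0] - 8 * vals[1] + 8 * vals[2] - vals[3]) / (12 * h)
                        # 1e-10 absolute floor: entries no pair touches have
                        # exact zero gradient and only FD roundoff (~1e-12)
                        tol = max(1e-6 * max(abs(fd), abs(grad[i, k])), 1e-10)
                        assert abs(fd - grad[i, k]) < tol


class TestTrain:
    def test_epochs_zero_returns_initialization(self, tiny_corpus):
        cfg = TrainingConfig(dim=4, window=2, epochs=0, seed=9)
        model = train(tiny_corpus, cfg)
        ref = initialize_model(model.vocab, cfg)
        np.testing.assert_array_equal(model.input_vectors, ref.input_vectors)
        assert not model.output_vectors.any()

    def test_default_configuration(self):
        cfg = TrainingConfig()
        assert cfg.dim == 100 and cfg.window == 25

    def test_seed_determinism(self, tiny_corpus):
        cfg = TrainingConfig(dim=6, window=2, epochs=3, seed=5)
        a = train(tiny_corpus, cfg)
        b = train(tiny_corpus, cfg)
        np.testing.assert_array_equal(a.input_vectors, b.input_vectors)
        np.testing.assert_array_equal(a.output_vectors, b.output_vectors)

    def test_different_seeds_differ(self, tiny_corpus):
        a = train(tiny_corpus, TrainingConfig(dim=6, window=2, epochs=3, seed=5))
        b = train(tiny_corpus, TrainingConfig(dim=6, window=2, epochs=3, seed=6))
        assert not np.array_equal(a.input_vectors, b.input_vectors)

    def test_objective_ascends_over_training(self):
        """Mean log objective on a fixed pair set rises from init, 5/5 seeds.

        The evaluation set mirrors the training objective: positives are
        observed co-occurrences, negatives are pairs that never co-occur
        anywhere in the corpus.
        """
        corpus = cooccurrence_toy_corpus(seed=0, n_sentences=200)
        for seed in range(5):
            cfg = TrainingConfig(dim=8, window=3, epochs=5, seed=seed)
            trained = train(corpus, cfg)
            init = initialize_model(trained.vocab, cfg)
            vocab = trained.vocab
            observed = set()
            for sent in corpus.sentences:
                for p in generate_pairs(sent, 3, vocab):
                    observed.add((p.center, p.context))
            pos = [TrainingPair(*wc) for wc in sorted(observed)[:50]]
            rng = np.random.default_rng(seed)
            neg = []
            while len(neg) < 50:
                w, c = (int(rng.integers(len(vocab))) for _ in range(2))
                if (w, c) not in observed and w != c:
                    neg.append(TrainingPair(w, c, "negative"))
            assert sgns_objective(trained, pos, neg) > sgns_objective(init, pos, neg)

    def test_cooccurring_tokens_closer_than_strangers(self):
        """Geometry recovery: always-co-occurring A,B end closer than A,Z."""
        for seed in range(1, 6):
            corpus = cooccurrence_toy_corpus(seed=seed)
            m = train(corpus, TrainingConfig(dim=10, window=5, epochs=5, seed=seed))
            assert (cosine_similarity(m.vector("AAA"), m.vector("BBB"))
                    > cosine_similarity(m.vector("AAA"), m.vector("ZZZ")))

    def test_symmetric_context_tokens_rank_high(self):
        """Tokens with identical context distributions (A and B) end more
        similar than the 95th percentile of unrelated cross-pool pairs."""
        corpus = cooccurrence_toy_corpus(seed=2)
        m = train(corpus, TrainingConfig(dim=10, window=5, epochs=5, seed=2))
        cab = cosine_similarity(m.vector("AAA"), m.vector("BBB"))
        ab_pool = ["AAA", "BBB"] + [t for t in m.vocab.tokens if t.endswith("A")]
        z_pool = ["ZZZ"] + [t for t in m.vocab.tokens if t.endswith("Z") and t != "ZZZ"]
        unrelated = [cosine_similarity(m.vector(x), m.vector(y))
                     for x in ab_pool for y in z_pool]
        assert cab > np.percentile(unrelated, 95)


class TestNearestNeighbors:
    def test_identical_vector_ranked_first(self, random_model):
        m = random_model
        m.input_vectors[3] = m.input_vectors[0]
        top = nearest_neighbors(m, m.vocab.tokens[0], 3)
        assert top[0][0] == m.vocab.tokens[3]
        assert abs(top[0][1] - 1.0) < 1e-12

    def test_orthogonal_similarity_zero(self):
        vocab = Vocabulary(tokens=["a", "b"], counts={"a": 1, "b": 1})
        inp = np.array([[1.0, 0.0], [0.0, 1.0]])
        m = EmbeddingModel(vocab=vocab, dim=2, input_vectors=inp,
                           output_vectors=np.zeros_like(inp))
        assert nearest_neighbors(m, "a", 1) == [("b", 0.0)]

    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        tokens = [f"w{i:02d}" for i in range(50)]
        vocab = Vocabulary(tokens=tokens, counts={t: 1 for t in tokens})
        V = rng.normal(size=(50, 7))
        m = EmbeddingModel(vocab=vocab, dim=7, input_vectors=V,
                           output_vectors=np.zeros_like(V))
        got = nearest_neighbors(m, "w00", 10)
        q = V[0] / np.linalg.norm(V[0])
        sims = {t: float(V[i] @ q / np.linalg.norm(V[i]))
                for i, t in enumerate(tokens) if t != "w00"}
        expect = sorted(sims.items(), key=lambda kv: (-kv[1], kv[0]))[:10]
        assert [t for t, _ in got] == [t for t, _ in expect]
        np.testing.assert_allclose([s for _, s in got], [s for _, s in expect],
                                   atol=1e-12)

    def test_oov_query_raises(self, random_model):
        with pytest.raises(KeyError):
            nearest_neighbors(random_model, "nope", 2)


class TestPersistence:
    def test_roundtrip(self, tmp_path, tiny_corpus):
        model = train(tiny_corpus, TrainingConfig(dim=5, window=2, epochs=2, seed=1))
        p = tmp_path / "m.txt"
        save_model(model, p)
        loaded = load_model(p)
        assert loaded.vocab.tokens == model.vocab.tokens
        np.testing.assert_allclose(loaded.input_vectors, model.input_vectors,
                                   atol=1e-6)

    def test_line_count_is_header_plus_rows(self, tmp_path, tiny_corpus):
        model = train(tiny_corpus, TrainingConfig(dim=5, window=2, epochs=0, seed=1))
        p = tmp_path / "m.txt"
        save_model(model, p)
        assert len(p.read_text().splitlines()) == len(model.vocab) + 1

    def test_header_row_mismatch_raises(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("10 2\na 0.1 0.2\nb 0.3 0.4\n")
        with pytest.raises(ValueError, match="W=10"):
            load_model(p)

    def test_non_numeric_entry_raises(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1 2\na 0.1 oops\n")
        with pytest.raises(ValueError):
            load_model(p)
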