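import numpy as np
import pytest

from memomol.cells import MemoryConfig
from memomol.generator import (GenerationPolicy, SmilesGenerator, TrainConfig,
                               get_next_character, train_generator)

SMALL_MEM = MemoryConfig(n_locations=10, word_size=8, controller_units=16,
                         embedding_length=12)


class TestPolicyConfigs:
    def test_policy_validation(self):
        with pytest.raises(ValueError):
            GenerationPolicy(epsilon=1.5)
        with pytest.raises(ValueError):
            GenerationPolicy(n_samples=0)
        with pytest.raises(ValueError):
            GenerationPolicy(max_length=0)

    def test_train_config_validation(self):
        with pytest.raises(ValueError):
            TrainConfig(iterations=0)
        with pytest.raises(ValueError):
            TrainConfig(learning_rate=-1)


class TestNextCharacter:
    def test_one_hot_passthrough(self, rng):
        dist = np.zeros(5)
        dist[3] = 1.0
        for eps in (0.0, 0.5, 1.0):
            pol = GenerationPolicy(epsilon=eps, n_samples=4)
            assert all(get_next_character(dist, pol, rng) == 3
                       for _ in range(20))

    def test_epsilon_zero_matches_direct_sampling(self):
        """Branch 1 only: empirical frequencies match the distribution."""
        dist = np.array([0.5, 0.3, 0.2])
        pol = GenerationPolicy(epsilon=0.0)
        rng = np.random.default_rng(7)
        n = 20000
        counts = np.bincount([get_next_character(dist, pol, rng)
                              for _ in range(n)], minlength=3)
        sigma = np.sqrt(n * dist * (1 - dist))
        assert np.all(np.abs(counts - n * dist) < 4 * sigma)

    def test_epsilon_one_matches_enumeration_oracle(self):
        """Two-token dist, n=3: exact marginal by enumerating all 2^3
        draw outcomes of the two-stage process."""
        p = 0.8
        # P(pick 0) = p^3 (all zeros) + (1 - p^3 - q^3)/2 (mixed sets)
        exact0 = p ** 3 + (1 - p ** 3 - (1 - p) ** 3) / 2
        dist = np.array([p, 1 - p])
        pol = GenerationPolicy(epsilon=1.0, n_samples=3)
        rng = np.random.default_rng(11)
        n = 20000
        hits = sum(get_next_character(dist, pol, rng) == 0 for _ in range(n))
        sigma = np.sqrt(n * exact0 * (1 - exact0))
        assert abs(hits - n * exact0) < 4 * sigma

    def test_malformed_distribution_rejected(self, rng):
        pol = GenerationPolicy()
        with pytest.raises(ValueError):
            get_next_character(np.array([0.5, 0.2]), pol, rng)
        with pytest.raises(ValueError):
            get_next_character(np.array([[0.5, 0.5]]), pol, rng)


class TestTraining:
    def test_single_string_convergence(self):
        """Cross-entropy of a deterministic sequence approaches zero."""
        corpus = ["CCOC(N)CC"] * 8
        cfg = TrainConfig(iterations=500, batch_size=8, eval_every=500,
                          eval_sample=10, learning_rate=5e-3, seed=0)
        gen, log = train_generator(corpus, "lstm", cfg, SMALL_MEM)
        final_losses = [e["loss"] for e in log][-3:]
        assert min(final_losses) < 0.01

    def test_identical_seeds_identical_traces(self, small_corpus):
        traces = []
        for _ in range(2):
            cfg = TrainConfig(iterations=60, batch_size=8, eval_every=60,
                              eval_sample=10, seed=42)
            _, log = train_generator(small_corpus[:100], "gru", cfg, SMALL_MEM)
            traces.append([e["loss"] for e in log])
        assert traces[0] == traces[1]

    def test_log_contains_expected_validity_entries(self, small_corpus):
        cfg = TrainConfig(iterations=90, batch_size=8, eval_every=30,
                          eval_sample=5, seed=1)
        _, log = train_generator(small_corpus[:50], "rnn", cfg, SMALL_MEM)
        assert sum("valid_pct" in e for e in log) == 90 // 30

    def test_empty_corpus_rejected(self, vocab):
        gen = SmilesGenerator("rnn", vocab, SMALL_MEM)
        with pytest.raises(ValueError):
            gen.train([], TrainConfig(iterations=1))


class TestGeneration:
    @pytest.fixture(scope="class")
    def trained(self, small_corpus):
        cfg = TrainConfig(iterations=400, batch_size=16, eval_every=400,
                          eval_sample=20, learning_rate=5e-3, seed=2)
        gen, _ = train_generator(small_corpus, "lstm", cfg, SMALL_MEM)
        return gen

    def test_count_and_cap_contracts(self, trained):
        pol = GenerationPolicy(max_length=15)
        batch = trained.generate(37, pol, seed=5)
        assert len(batch) == 37
        assert all(len(trained.vocab.tokenize(s)) <= 15 for s in batch)

    def test_fixed_seed_reproducible(self, trained):
        a = trained.generate(25, seed=9)
        b = trained.generate(25, seed=9)
        assert list(a) == list(b)

    def test_forced_end_token_gives_empty_strings(self, vocab):
        gen = SmilesGenerator("rnn", vocab, SMALL_MEM, seed=0)
        gen.model.bo.data[vocab.end_index] = 50.0  # end emitted w.p. ~1
        batch = gen.generate(10, GenerationPolicy(epsilon=0.0), seed=0)
        assert list(batch) == [""] * 10
        assert batch.n_truncated == 0

    def test_checkpoint_roundtrip_reproduces_generation(self, trained,
                                                        tmp_path):
        path = tmp_path / "gen.ckpt"
        trained.save(path)
        loaded = SmilesGenerator.load(path)
        assert list(trained.generate(20, seed=3)) == \
            list(loaded.generate(20, seed=3))
        assert loaded.arch == trained.arch
        assert loaded.vocab.tokens == trained.vocab.tokens

    def test_rollout_consistent_with_sampling(self, trained):
        pol = GenerationPolicy(max_length=20)
        strings, ce = trained.rollout(8, pol, np.random.default_rng(4))
        assert len(strings) == 8
        assert ce.data.shape == (8,)
        assert np.all(ce.data >= 0)  # negative log-likelihoods
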