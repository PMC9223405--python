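import numpy as np
import pytest

from memomol.predictor import (PredictorConfig, PropertyPredictor,
                               encode_for_predictor, train_predictor)
from memomol.tokenizer import build_vocabulary

FAST = dict(epochs=8, batch_size=32, learning_rate=2e-3)


class TestEncoding:
    def test_padding_arithmetic(self, vocab):
        out = encode_for_predictor("CCO", vocab, 121)
        assert out.shape == (121,)
        assert np.sum(out != vocab.chem_size) == 3
        assert np.all(out[3:] == vocab.chem_size)

    def test_exact_length_boundary(self, vocab):
        s = "C" * 121
        out = encode_for_predictor(s, vocab, 121)
        assert np.all(out != vocab.chem_size)

    def test_unknown_token_maps_to_extra_slot(self):
        v = build_vocabulary(["CCO"])
        out = encode_for_predictor("CSO", v, 10)
        assert out[1] == v.unk_index  # the 46th slot in the default setup

    def test_overflow_modes(self, vocab):
        s = "C" * 200
        assert encode_for_predictor(s, vocab, 121).shape == (121,)
        with pytest.raises(ValueError):
            encode_for_predictor(s, vocab, 121, overflow="error")


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            PredictorConfig(dropout=1.0)
        with pytest.raises(ValueError):
            PredictorConfig(n_conv_layers=3)  # mismatched channel list
        with pytest.raises(ValueError):
            PredictorConfig(input_length=0)

    def test_default_shape_follows_full_scale_setup(self):
        cfg = PredictorConfig()
        assert cfg.input_length == 121
        assert cfg.embedding_width == 46
        assert cfg.n_conv_layers == 5
        assert cfg.dropout == 0.5


class TestTraining:
    def test_constant_target_converges(self, corpus):
        """Degenerate regression: the optimum is the constant itself."""
        c = 2.5
        pairs = [(s, c) for s in corpus[:200]]
        # dropout off: the check targets the network/optimizer, and
        # dropout noise would set the floor, not the model
        model, mse = train_predictor(
            pairs, PredictorConfig(seed=0, epochs=25, batch_size=32,
                                   learning_rate=3e-3, dropout=0.0))
        assert mse < 1e-3
        assert model.predict(corpus[0]) == pytest.approx(c, abs=0.1)

    def test_too_few_pairs_rejected(self, vocab):
        model = PropertyPredictor(vocab)
        with pytest.raises(ValueError):
            model.fit(["CC"] * 5, [1.0] * 5)

    def test_nonfinite_targets_rejected(self, vocab, corpus):
        model = PropertyPredictor(vocab)
        with pytest.raises(ValueError):
            model.fit(corpus[:20], [np.nan] * 20)

    def test_shuffled_targets_mse_near_variance(self, corpus, vocab):
        """With target-input pairing destroyed the best prediction is
        the mean, so held-out MSE approaches the target variance."""
        rng = np.random.default_rng(0)
        smiles = corpus[:600]
        targets = np.array([float(len(s)) for s in smiles])
        rng.shuffle(targets)  # breaks the pairing, keeps the marginal
        model = PropertyPredictor(vocab, PredictorConfig(
            seed=1, epochs=4, batch_size=64, learning_rate=1e-3))
        mse = model.fit(smiles, targets)
        var = np.var(targets)
        assert mse == pytest.approx(var, rel=0.3)


class TestInference:
    @pytest.fixture(scope="class")
    def fitted(self, corpus, vocab):
        pairs = [(s, float(len(s))) for s in corpus[:400]]
        model = PropertyPredictor(vocab, PredictorConfig(seed=3, **FAST))
        model.fit([p[0] for p in pairs], [p[1] for p in pairs])
        return model

    def test_deterministic(self, fitted, corpus):
        assert fitted.predict(corpus[0]) == fitted.predict(corpus[0])

    def test_batch_equals_elementwise(self, fitted, corpus):
        batch = fitted.predict(corpus[:5])
        singles = [fitted.predict(s) for s in corpus[:5]]
        np.testing.assert_allclose(batch, singles, rtol=1e-6)

    def test_accepts_invalid_strings(self, fitted):
        assert np.isfinite(fitted.predict("C((not-smiles"))

    def test_save_load_roundtrip(self, fitted, corpus, tmp_path):
        path = tmp_path / "pred.ckpt"
        fitted.save(path)
        loaded = PropertyPredictor.load(path)
        assert loaded.predict(corpus[0]) == pytest.approx(
            fitted.predict(corpus[0]), rel=1e-6)

    def test_scorer_callable(self, fitted, corpus):
        scorer = fitted.as_scorer()
        assert scorer(corpus[0]) == pytest.approx(fitted.predict(corpus[0]))
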