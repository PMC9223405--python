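import math

import numpy as np
import pytest

from memomol.fixtures import toy_property_oracle
from memomol.generator import GenerationPolicy
from memomol.nn.optim import Adam
from memomol.rl import (RewardConfig, bias_generator, bias_step,
                        predicted_loss)


class TestPredictedLoss:
    def test_zero_property(self):
        assert predicted_loss(0.0, 0.5) == 1.0
        assert predicted_loss(0.0, -3.0) == 1.0

    def test_closed_form(self):
        assert predicted_loss(2.0, 0.5) == pytest.approx(math.e)

    def test_zero_s_boundary(self):
        # s = 0 is rejected by RewardConfig, but the function itself is
        # total: no property gradient, constant 1
        assert np.all(predicted_loss(np.array([-5.0, 0.0, 7.0]), 0.0) == 1.0)

    def test_overflow_clipped(self):
        assert np.isfinite(predicted_loss(1e6, 1.0))
        assert predicted_loss(1e6, 1.0) == pytest.approx(np.exp(30.0))

    def test_vectorized(self):
        out = predicted_loss(np.array([0.0, 2.0]), 0.5)
        np.testing.assert_allclose(out, [1.0, math.e])


class TestRewardConfig:
    def test_sign_convention_enforced(self):
        with pytest.raises(ValueError):
            RewardConfig(direction="minimize", s=-0.5)
        with pytest.raises(ValueError):
            RewardConfig(direction="maximize", s=0.5)
        RewardConfig(direction="minimize", s=0.5)
        RewardConfig(direction="maximize", s=-0.5)

    def test_zero_s_rejected(self):
        with pytest.raises(ValueError):
            RewardConfig(direction="minimize", s=0.0)

    def test_for_direction_applies_sign(self):
        assert RewardConfig.for_direction("minimize", 0.3).s == 0.3
        assert RewardConfig.for_direction("maximize", 0.3).s == -0.3

    def test_invalid_choices_rejected(self):
        with pytest.raises(ValueError):
            RewardConfig(direction="sideways")
        with pytest.raises(ValueError):
            RewardConfig(loss_mode="ppo")
        with pytest.raises(ValueError):
            RewardConfig(invalid_policy="ignore")


class TestBiasStep:
    def test_seeded_steps_are_deterministic(self, bias_base_generator):
        pol = GenerationPolicy(max_length=30)
        diags = []
        for _ in range(2):
            g = bias_base_generator.clone()
            cfg = RewardConfig.for_direction("minimize", 0.25, batch_size=12,
                                             seed=0)
            opt = Adam(g.model.store.tensors(), lr=cfg.learning_rate)
            rng = np.random.default_rng(99)
            diags.append(bias_step(g, toy_property_oracle, cfg, pol, opt,
                                   rng))
        assert diags[0] == diags[1]

    def test_diagnostics_fields(self, bias_base_generator):
        g = bias_base_generator.clone()
        cfg = RewardConfig.for_direction("maximize", 0.25, batch_size=8,
                                         seed=1)
        opt = Adam(g.model.store.tensors(), lr=cfg.learning_rate)
        d = bias_step(g, toy_property_oracle, cfg,
                      GenerationPolicy(max_length=25), opt,
                      np.random.default_rng(0))
        for key in ("mean_p", "median_p", "mean_loss", "valid_pct",
                    "mean_length"):
            assert np.isfinite(d[key])


class TestBiasGenerator:
    def test_history_length_matches_steps(self, bias_base_generator):
        g = bias_base_generator.clone()
        cfg = RewardConfig.for_direction("minimize", 0.25, batch_size=8,
                                         seed=2)
        hist = bias_generator(g, toy_property_oracle, cfg, 5,
                              GenerationPolicy(max_length=25))
        assert len(hist) == 5
        assert [h["step"] for h in hist] == [1, 2, 3, 4, 5]

    def test_divergence_guard_stops_early(self, bias_base_generator):
        g = bias_base_generator.clone()
        # a floor above the achievable validity trips immediately
        cfg = RewardConfig.for_direction("minimize", 0.25, batch_size=8,
                                         seed=2, validity_floor=1.0)
        hist = bias_generator(g, toy_property_oracle, cfg, 50,
                              GenerationPolicy(max_length=25))
        assert len(hist) < 50
        assert hist[-1].get("stopped_early") is True

    def test_minimize_shifts_property_down(self, bias_base_generator):
        """A short biasing run already moves the mean heavy-atom count
        of generated strings downward."""
        g = bias_base_generator.clone()
        pol = GenerationPolicy(max_length=40)
        base = g.generate(200, pol, seed=123)
        base_mean = np.mean([toy_property_oracle(s) for s in base])
        cfg = RewardConfig.for_direction(
            "minimize", 0.25, batch_size=24, seed=3, learning_rate=5e-4,
            invalid_policy="penalty", penalty_value=30.0)
        bias_generator(g, toy_property_oracle, cfg, 80, pol)
        biased = g.generate(200, pol, seed=321)
        biased_mean = np.mean([toy_property_oracle(s) for s in biased])
        assert biased_mean < base_mean
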