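import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import memomol.nn.autodiff as ad
from memomol.cells import (MemoryConfig, SequenceModel, cell_step,
                           content_weights, dnc_allocation,
                           dnc_temporal_update, make_cell, memory_read,
                           memory_write, ntm_address, stack_update)
from memomol.nn.optim import ParamStore

TINY = MemoryConfig(n_locations=8, word_size=6, controller_units=12,
                    embedding_length=8)


class TestStack:
    def test_noop_identity(self, rng):
        S = rng.random((5, 4))
        out = stack_update(S, np.array([0.0, 0.0, 1.0]), rng.random(4))
        np.testing.assert_allclose(out, S)

    def test_push_then_pop_restores(self, rng):
        S = rng.random((5, 4))
        S[-1] = 0.0  # deepest row zero, so push/pop is exactly inverse
        v = rng.random(4)
        pushed = stack_update(S, np.array([1.0, 0.0, 0.0]), v)
        np.testing.assert_allclose(pushed[0], v)
        popped = stack_update(pushed, np.array([0.0, 1.0, 0.0]), v)
        np.testing.assert_allclose(popped, S, atol=1e-12)

    def test_convex_blend_on_top_row(self, rng):
        S = rng.random((5, 4))
        v = rng.random(4)
        out = stack_update(S, np.array([0.5, 0.0, 0.5]), v)
        np.testing.assert_allclose(out[0], 0.5 * v + 0.5 * S[0])

    def test_action_must_be_distribution(self, rng):
        with pytest.raises(ValueError):
            stack_update(rng.random((5, 4)), np.array([0.9, 0.9, 0.1]),
                         rng.random(4))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_one_hot_actions_emulate_classical_stack(self, seed):
        """Soft stack with hard actions == bounded list-based stack."""
        rng = np.random.default_rng(seed)
        depth, width = 6, 3
        soft = np.zeros((depth, width))
        hard = []
        for _ in range(30):
            op = rng.integers(3)
            action = np.eye(3)[op]
            v = rng.random(width)
            soft = stack_update(soft, action, v)
            if op == 0:
                hard.insert(0, v.copy())
                hard = hard[:depth]
            elif op == 1 and hard:
                hard.pop(0)
            expected = np.zeros((depth, width))
            for i, row in enumerate(hard):
                expected[i] = row
            np.testing.assert_allclose(soft, expected, atol=1e-12)


class TestContentAddressing:
    def test_sharp_key_gives_one_hot(self):
        mem = np.eye(4, 4)
        w = content_weights(mem[2], 1e3, mem)
        np.testing.assert_allclose(w, np.eye(4)[2], atol=1e-6)

    def test_zero_beta_uniform(self, rng):
        w = content_weights(rng.random(6), 0.0, rng.random((5, 6)))
        np.testing.assert_allclose(w, np.full(5, 0.2), atol=1e-12)

    def test_weights_normalized(self, rng):
        w = content_weights(rng.standard_normal(6), 2.0,
                            rng.standard_normal((7, 6)))
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_zero_vectors_handled(self):
        w = content_weights(np.zeros(4), 5.0, np.zeros((3, 4)))
        assert np.all(np.isfinite(w))
        assert w.sum() == pytest.approx(1.0, abs=1e-6)

    def test_negative_beta_rejected(self, rng):
        with pytest.raises(ValueError):
            content_weights(rng.random(4), -1.0, rng.random((3, 4)))


class TestLocationAddressing:
    def test_neutral_elements_pass_content_through(self, rng):
        c = rng.dirichlet(np.ones(6))
        p = rng.dirichlet(np.ones(6))
        out = ntm_address(p, c, 1.0, np.array([0.0, 1.0, 0.0]), 1.0)
        np.testing.assert_allclose(out, c, atol=1e-6)

    def test_closed_gate_keeps_previous(self, rng):
        c = rng.dirichlet(np.ones(6))
        p = rng.dirichlet(np.ones(6))
        out = ntm_address(p, c, 0.0, np.array([0.0, 1.0, 0.0]), 1.0)
        np.testing.assert_allclose(out, p, atol=1e-6)

    def test_circular_shift(self):
        w = np.zeros(5)
        w[1] = 1.0
        out = ntm_address(w, w, 1.0, np.array([0.0, 0.0, 1.0]), 1.0)
        assert np.argmax(out) == 2
        out = ntm_address(w, w, 1.0, np.array([1.0, 0.0, 0.0]), 1.0)
        assert np.argmax(out) == 0
        # wrap-around
        w = np.zeros(5)
        w[4] = 1.0
        out = ntm_address(w, w, 1.0, np.array([0.0, 0.0, 1.0]), 1.0)
        assert np.argmax(out) == 0

    def test_gamma_below_one_rejected(self, rng):
        c = rng.dirichlet(np.ones(4))
        with pytest.raises(ValueError):
            ntm_address(c, c, 0.5, np.array([0.0, 1.0, 0.0]), 0.5)

    def test_sharpening_concentrates(self, rng):
        c = rng.dirichlet(np.ones(6))
        soft = ntm_address(c, c, 1.0, np.array([0.0, 1.0, 0.0]), 1.0)
        sharp = ntm_address(c, c, 1.0, np.array([0.0, 1.0, 0.0]), 8.0)
        assert sharp.max() > soft.max()


class TestMemoryReadWrite:
    def test_full_erase_zeroes_row(self, rng):
        mem = rng.random((4, 5))
        w = np.eye(4)[1]
        out = memory_write(mem, w, np.ones(5), np.zeros(5))
        np.testing.assert_allclose(out[1], 0.0, atol=1e-12)
        np.testing.assert_allclose(out[[0, 2, 3]], mem[[0, 2, 3]])

    def test_identity_write(self, rng):
        mem = rng.random((4, 5))
        out = memory_write(mem, rng.dirichlet(np.ones(4)),
                           np.zeros(5), np.zeros(5))
        np.testing.assert_allclose(out, mem)

    def test_write_then_read(self, rng):
        mem = rng.random((4, 5))
        w = np.eye(4)[2]
        a = rng.random(5)
        out = memory_write(mem, w, np.ones(5), a)
        np.testing.assert_allclose(memory_read(out, w), a, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            memory_read(rng.random((4, 5)), rng.dirichlet(np.ones(3)))


def _alloc_oracle(usage):
    """Literal evaluation of the sorted-product allocation formula."""
    order = np.argsort(usage, kind="stable")
    a = np.zeros_like(usage)
    prod = 1.0
    for j, loc in enumerate(order):
        a[loc] = (1.0 - usage[loc]) * prod
        prod *= usage[loc]
    return a


class TestAllocation:
    def test_all_free_allocates_lowest_index(self):
        np.testing.assert_allclose(dnc_allocation(np.zeros(5)), np.eye(5)[0])

    def test_all_used_allocates_nothing(self):
        np.testing.assert_allclose(dnc_allocation(np.ones(5)), np.zeros(5))

    def test_two_location_case(self):
        np.testing.assert_allclose(dnc_allocation(np.array([0.5, 0.0])),
                                   _alloc_oracle(np.array([0.5, 0.0])))

    def test_matches_bruteforce_oracle(self, rng):
        for _ in range(50):
            u = rng.random(8)
            a = dnc_allocation(u)
            np.testing.assert_allclose(a, _alloc_oracle(u), atol=1e-12)
            assert np.all(a >= 0) and a.sum() <= 1 + 1e-9

    def test_out_of_range_usage_rejected(self):
        with pytest.raises(ValueError):
            dnc_allocation(np.array([0.5, 1.5]))


class TestTemporalLink:
    def test_first_write_keeps_link_zero(self):
        L, p = dnc_temporal_update(np.zeros((4, 4)), np.zeros(4),
                                   np.eye(4)[1])
        np.testing.assert_allclose(L, 0.0)
        np.testing.assert_allclose(p, np.eye(4)[1])

    def test_two_one_hot_writes(self):
        L, p = dnc_temporal_update(np.zeros((4, 4)), np.zeros(4), np.eye(4)[0])
        L, p = dnc_temporal_update(L, p, np.eye(4)[2])
        expected = np.zeros((4, 4))
        expected[2, 0] = 1.0
        np.testing.assert_allclose(L, expected)

    def test_diagonal_forced_zero(self, rng):
        L = rng.random((5, 5)) * 0.1
        np.fill_diagonal(L, 0.0)
        w = rng.dirichlet(np.ones(5))
        p = rng.dirichlet(np.ones(5)) * 0.5
        L2, _ = dnc_temporal_update(L, p, w)
        np.testing.assert_allclose(np.diag(L2), 0.0)


class TestCells:
    @pytest.mark.parametrize("arch", ["rnn", "gru", "lstm", "stackrnn",
                                      "ntm", "dnc"])
    def test_step_deterministic(self, arch):
        m = SequenceModel(arch, 10, 10, TINY, seed=3)
        tok = np.array([1, 2, 3])
        s1 = m.init_state(3)
        s2 = m.init_state(3)
        l1, _ = cell_step(m, s1, tok)
        l2, _ = cell_step(m, s2, tok)
        np.testing.assert_array_equal(l1.data, l2.data)

    def test_unknown_arch_rejected(self):
        with pytest.raises(ValueError):
            make_cell("transformer", ParamStore(), 8, TINY,
                      np.random.default_rng(0))

    @pytest.mark.parametrize("arch", ["ntm", "dnc"])
    def test_weight_invariants_after_random_steps(self, arch, rng):
        m = SequenceModel(arch, 10, 10, TINY, seed=7)
        state = m.init_state(4)
        for _ in range(40):
            _, state = m.step(rng.integers(0, 10, size=4), state)
            read_ws = state[3]
            for w in read_ws:
                assert np.all(w.data >= -1e-6)
                sums = w.data.sum(-1)
                if arch == "ntm":
                    np.testing.assert_allclose(sums, 1.0, atol=1e-5)
                else:
                    # DNC weightings are sub-stochastic: read modes mix
                    # content with (possibly empty) temporal links
                    assert np.all(sums <= 1 + 1e-5)
        if arch == "dnc":
            link = state[7].data
            np.testing.assert_allclose(
                np.diagonal(link, axis1=1, axis2=2), 0.0, atol=1e-7)
            assert np.all(link.sum(-1) <= 1 + 1e-5)
            assert np.all(link.sum(-2) <= 1 + 1e-5)
            usage = state[6].data
            assert np.all((usage >= -1e-6) & (usage <= 1 + 1e-6))

    def test_stackrnn_gradient_check(self):
        """Backprop through the soft stack agrees with finite differences."""
        cfg = MemoryConfig(n_locations=4, word_size=5, controller_units=6,
                           embedding_length=5)
        m = SequenceModel("stackrnn", 5, 5, cfg, seed=3, dtype=np.float64)
        toks = [np.array([1, 2]), np.array([3, 0])]

        def loss_fn():
            st = m.init_state(2)
            total = None
            for t in toks:
                logits, st = m.step(t, st)
                term = ad.tsum(ad.tanh(logits))
                total = term if total is None else total + term
            return total

        loss = loss_fn()
        m.store.zero_grad()
        loss.backward()
        rng = np.random.default_rng(0)
        for name, t in m.store.items():
            flat = t.data.ravel()
            for i in rng.choice(flat.size, size=min(3, flat.size),
                                replace=False):
                eps, old = 1e-6, flat[i]
                flat[i] = old + eps
                lp = loss_fn().item()
                flat[i] = old - eps
                lm = loss_fn().item()
                flat[i] = old
                num = (lp - lm) / (2 * eps)
                ana = t.grad.ravel()[i]
                assert num == pytest.approx(ana, rel=1e-4, abs=1e-8), name

    def test_memory_config_validation(self):
        with pytest.raises(ValueError):
            MemoryConfig(n_locations=0)
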