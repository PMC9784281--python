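"""Replay memory, epsilon-greedy selection, TD(0) targets, gradient step."""

import numpy as np
import pytest
from scipy import stats

from lesionrl.dqn import (
    Adam,
    EpsilonSchedule,
    ReplayBuffer,
    Transition,
    build_q_network,
    encode_batch,
    epsilon_at,
    q_forward,
    select_action,
    td_targets,
    train_batch,
)
from lesionrl.env import Action, AgentState, build_grid, initial_state, step

from conftest import make_image


def random_transitions(image, block_size, n, rng):
    grid = build_grid(image, block_size)
    out = []
    for _ in range(n):
        state = AgentState(image, grid, int(rng.integers(grid.n_rows)),
                           int(rng.integers(grid.n_cols)))
        action = Action(int(rng.integers(3)) + 1)
        o = step(state, action)
        out.append(Transition(state, action, o.reward, o.next_state))
    return out


class TestReplayBuffer:
    def test_fifo_eviction_at_paper_capacity(self, tiny_image, tiny_block_size):
        buf = ReplayBuffer(capacity=15_000)
        s = initial_state(tiny_image, tiny_block_size)
        o = step(s, Action.STAY)
        first = Transition(s, Action.STAY, o.reward, o.next_state)
        buf.push(first)
        filler = Transition(s, Action.DOWN, step(s, Action.DOWN).reward,
                            step(s, Action.DOWN).next_state)
        for _ in range(15_000):
            buf.push(filler)
        assert len(buf) == 15_000
        assert all(buf[i] is not first for i in range(3))  # oldest evicted

    def test_order_preserved(self, tiny_image, tiny_block_size):
        rng = np.random.default_rng(0)
        ts = random_transitions(tiny_image, tiny_block_size, 6, rng)
        buf = ReplayBuffer(capacity=4)
        for t in ts:
            buf.push(t)
        assert [buf[i] for i in range(4)] == ts[2:]

    def test_sample_requires_enough_experience(self, tiny_image, tiny_block_size):
        buf = ReplayBuffer(capacity=10)
        ts = random_transitions(tiny_image, tiny_block_size, 5,
                                np.random.default_rng(1))
        for t in ts:
            buf.push(t)
        with pytest.raises(ValueError, match="buffer holds"):
            buf.sample(6, np.random.default_rng(0))
        got = buf.sample(5, np.random.default_rng(0))
        assert sorted(map(id, got)) == sorted(map(id, ts))

    def test_sampling_is_uniform(self, tiny_image, tiny_block_size):
        """Chi-square goodness of fit on per-entry selection frequencies."""
        buf = ReplayBuffer(capacity=1000)
        ts = random_transitions(tiny_image, tiny_block_size, 1000,
                                np.random.default_rng(2))
        for t in ts:
            buf.push(t)
        rng = np.random.default_rng(3)
        counts = np.zeros(1000)
        index_of = {id(t): i for i, t in enumerate(ts)}
        for _ in range(1000):
            for t in buf.sample(100, rng):
                counts[index_of[id(t)]] += 1
        assert stats.chisquare(counts).pvalue > 1e-3


class TestSelectAction:
    def test_greedy_argmax_and_tie_break(self):
        rng = np.random.default_rng(0)
        assert select_action(np.array([1.0, 3.0, 2.0]), 0.0, rng) is Action.DOWN
        assert select_action(np.array([2.0, 2.0, 0.0]), 0.0, rng) is Action.STAY

    def test_pure_exploration_is_uniform(self):
        rng = np.random.default_rng(1)
        q = np.array([5.0, 0.0, 0.0])
        n = 30_000
        counts = np.zeros(3)
        for _ in range(n):
            counts[select_action(q, 1.0, rng).index] += 1
        # 99% two-sided binomial interval around n/3
        half = 2.576 * np.sqrt(n * (1 / 3) * (2 / 3))
        assert np.all(np.abs(counts - n / 3) < half)


class TestEpsilonSchedule:
    def test_paper_schedule_values(self):
        sched = EpsilonSchedule()
        assert epsilon_at(sched, 0) == pytest.approx(0.7)
        assert epsilon_at(sched, 10) == pytest.approx(0.699)
        assert epsilon_at(sched, 10_000_000) == pytest.approx(1e-4)

    def test_non_increasing_and_bounded(self):
        sched = EpsilonSchedule(epsilon_initial=0.5, decay_per_episode=0.01,
                                epsilon_min=0.05)
        values = [epsilon_at(sched, e) for e in range(0, 200, 7)]
        assert all(a >= b for a, b in zip(values, values[1:]))
        assert all(0.05 <= v <= 0.5 for v in values)


class TestTDTargets:
    def test_gamma_zero_reduces_to_rewards(self, tiny_image, tiny_block_size):
        batch = random_transitions(tiny_image, tiny_block_size, 20,
                                   np.random.default_rng(4))
        net = build_q_network(16, 16, seed=0, hidden_sizes=(16, 8))
        targets = td_targets(batch, net, gamma=0.0)
        assert np.array_equal(targets, [t.reward for t in batch])

    def test_batched_targets_match_elementwise_loop(self, tiny_image,
                                                    tiny_block_size):
        """Independent oracle: one forward pass per transition."""
        batch = random_transitions(tiny_image, tiny_block_size, 50,
                                   np.random.default_rng(5))
        net = build_q_network(16, 16, seed=1, hidden_sizes=(16, 8))
        gamma = 0.99
        targets = td_targets(batch, net, gamma)
        for t, got in zip(batch, targets):
            q_next = q_forward(net, encode_batch([t.next_state]))[0]
            assert got == pytest.approx(t.reward + gamma * q_next.max(), rel=1e-5)


class TestTrainBatch:
    def test_loss_is_nonnegative_and_pre_step(self, tiny_image, tiny_block_size):
        batch = random_transitions(tiny_image, tiny_block_size, 8,
                                   np.random.default_rng(6))
        net = build_q_network(16, 16, seed=2, hidden_sizes=(16, 8))
        opt = Adam(net, lr=1e-4)
        assert train_batch(net, opt, batch, gamma=0.9) >= 0.0

    def test_repeated_training_fits_single_transition(self, tiny_image,
                                                      tiny_block_size):
        """With gamma=0 the target is the reward; Q(s, a) converges to it."""
        s = initial_state(tiny_image, tiny_block_size)
        o = step(s, Action.DOWN)
        t = Transition(s, Action.DOWN, o.reward, o.next_state)
        net = build_q_network(16, 16, seed=3, hidden_sizes=(16, 8))
        opt = Adam(net, lr=1e-4)
        for _ in range(2000):
            q = q_forward(net, encode_batch([s]))[0]
            if abs(q[Action.DOWN.index] - t.reward) < 1e-2:
                break
            train_batch(net, opt, [t], gamma=0.0)
        q = q_forward(net, encode_batch([s]))[0]
        assert abs(q[Action.DOWN.index] - t.reward) < 1e-2

    def test_fixed_seed_training_is_bitwise_reproducible(self, tiny_image,
                                                         tiny_block_size):
        batch = random_transitions(tiny_image, tiny_block_size, 8,
                                   np.random.default_rng(7))

        def run():
            net = build_q_network(16, 16, seed=4, hidden_sizes=(16, 8))
            opt = Adam(net, lr=1e-3)
            for _ in range(5):
                train_batch(net, opt, batch, gamma=0.9)
            return net

        a, b = run(), run()
        assert all(np.array_equal(p, q)
                   for p, q in zip(a.parameters(), b.parameters()))


def test_transition_rejects_off_scheme_reward():
    img = make_image(16, lesion_pixels=((10, 10),))
    s = initial_state(img, 4)
    with pytest.raises(ValueError, match="reward"):
        Transition(s, Action.STAY, 0.25, s)
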