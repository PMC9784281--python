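"""Deep Q network, replay memory, and the TD(0) learning step.

The agent approximates the action-value function Q(s, a) with a small
convolutional network (:mod:`lesionrl.nn`) mapping the two-channel
observation to three Q-values, one per action.  Behavior is
epsilon-greedy with a linearly decaying epsilon; experience is stored in
a FIFO replay buffer and replayed in uniformly drawn minibatches.  The
learning target is the one-step Bellman (TD(0)) value

    Q_target = r + gamma * max_a Q(s', a)

computed from the live network and treated as a constant, and the loss
is the batch-mean absolute error on the taken action's Q-value,
minimized with Adam (learning rate 1e-4).  The MDP has no terminal
states, so no terminal zeroing is applied.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .env import Action, AgentState, encode_observation, REWARD_VALUES
from .nn import Adam, ConvNet, ConvNetSpec

__all__ = [
    "Transition",
    "ReplayBuffer",
    "EpsilonSchedule",
    "build_q_network",
    "q_network_spec",
    "q_forward",
    "select_action",
    "epsilon_at",
    "encode_batch",
    "td_targets",
    "train_batch",
]

N_ACTIONS = 3


@dataclass(frozen=True)
class Transition:
    """One (s, a, r, s') experience tuple."""

    state: AgentState
    action: Action
    reward: float
    next_state: AgentState

    def __post_init__(self) -> None:
        if self.reward not in REWARD_VALUES:
            raise ValueError(f"reward {self.reward} outside the reward scheme")


class ReplayBuffer:
    """FIFO experience store; the oldest transition is evicted first."""

    def __init__(self, capacity: int = 15_000):
        if capacity < 1:
            raise ValueError("capacity must be positive")
        self.capacity = capacity
        self._entries: deque[Transition] = deque(maxlen=capacity)

    def push(self, t: Transition) -> None:
        self._entries.append(t)

    def __len__(self) -> int:
        return len(self._entries)

    def __getitem__(self, i: int) -> Transition:
        return self._entries[i]

    def sample(self, n: int, rng: np.random.Generator) -> list[Transition]:
        """``n`` transitions drawn uniformly without replacement."""
        if n > len(self._entries):
            raise ValueError(
                f"batch of {n} requested but buffer holds {len(self._entries)}"
            )
        idx = rng.choice(len(self._entries), size=n, replace=False)
        return [self._entries[int(i)] for i in idx]


@dataclass(frozen=True)
class EpsilonSchedule:
    """Linear epsilon decay per episode, floored at ``epsilon_min``."""

    epsilon_initial: float = 0.7
    decay_per_episode: float = 1e-4
    epsilon_min: float = 1e-4

    def __post_init__(self) -> None:
        if not (0.0 <= self.epsilon_min <= self.epsilon_initial <= 1.0):
            raise ValueError("need 0 <= epsilon_min <= epsilon_initial <= 1")
        if self.decay_per_episode < 0:
            raise ValueError("decay must be non-negative")


def epsilon_at(schedule: EpsilonSchedule, episode: int) -> float:
    if episode < 0:
        raise ValueError("episode must be >= 0")
    return max(schedule.epsilon_min,
               schedule.epsilon_initial - episode * schedule.decay_per_episode)


def q_network_spec(height: int = 240, width: int = 240,
                   hidden_sizes: tuple[int, ...] = (512, 128)) -> ConvNetSpec:
    """The DQN architecture: 4 stride-2 conv layers (32 ch, ELU) + FC head."""
    return ConvNetSpec(input_channels=2, input_height=height, input_width=width,
                       conv_channels=32, n_conv_layers=4,
                       hidden_sizes=hidden_sizes, output_size=N_ACTIONS)


def build_q_network(height: int = 240, width: int = 240,
                    seed: int | np.random.SeedSequence = 0,
                    hidden_sizes: tuple[int, ...] = (512, 128)) -> ConvNet:
    return ConvNet(q_network_spec(height, width, hidden_sizes), seed=seed)


def load_q_network(path, height: int, width: int) -> ConvNet:
    """Load saved weights, inferring the fully connected head widths."""
    with np.load(path) as d:
        state = dict(d)
    n_fc = sum(1 for k in state if k.endswith(".w") and k.startswith("fc"))
    hidden = tuple(state[f"fc{i}.w"].shape[1] for i in range(n_fc - 1))
    net = build_q_network(height, width, seed=0, hidden_sizes=hidden)
    net.load_state_dict(state)
    return net


def encode_batch(states: list[AgentState]) -> np.ndarray:
    return np.stack([encode_observation(s) for s in states])


def q_forward(net: ConvNet, obs: np.ndarray) -> np.ndarray:
    """Q-values for one observation (3,) or a batch (N, 3)."""
    obs = np.asarray(obs, dtype=np.float32)
    single = obs.ndim == 3
    if single:
        obs = obs[None]
    q = net.forward(obs)
    return q[0] if single else q


def greedy_action(q: np.ndarray) -> Action:
    """Argmax action; ties break toward the lowest action code."""
    return Action(int(np.argmax(q)) + 1)


def select_action(q: np.ndarray, epsilon: float, rng: np.random.Generator) -> Action:
    """Epsilon-greedy: explore uniformly with probability ``epsilon``."""
    if not 0.0 <= epsilon <= 1.0:
        raise ValueError("epsilon must lie in [0, 1]")
    if rng.random() < epsilon:
        return Action(int(rng.integers(N_ACTIONS)) + 1)
    return greedy_action(q)


def td_targets(batch: list[Transition], net: ConvNet, gamma: float) -> np.ndarray:
    """One-step Bellman targets r + gamma * max_a Q(s', a), no gradient."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    rewards = np.array([t.reward for t in batch], dtype=np.float32)
    if gamma == 0.0:
        return rewards
    next_obs = encode_batch([t.next_state for t in batch])
    next_q = net.forward(next_obs)
    return rewards + np.float32(gamma) * next_q.max(axis=1)


def train_batch(net: ConvNet, optimizer: Adam, batch: list[Transition],
                gamma: float) -> float:
    """One Adam step on the batch L1 loss; returns the pre-step loss.

    Only the taken action's Q-value enters the loss; the Bellman target
    is a constant with respect to the parameters.
    """
    if not batch:
        raise ValueError("batch must be nonempty")
    targets = td_targets(batch, net, gamma)
    obs = encode_batch([t.state for t in batch])
    q = net.forward(obs, keep_cache=True)
    taken = np.array([t.action.index for t in batch])
    rows = np.arange(len(batch))
    residual = q[rows, taken] - targets
    loss = float(np.abs(residual).mean())
    dout = np.zeros_like(q)
    dout[rows, taken] = np.sign(residual) / len(batch)
    grads = net.backward(dout)
    optimizer.step(grads)
    return loss
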