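"""Exact tabular solution of a single-image gridworld MDP.

With 16 blocks and 3 actions the MDP is tiny, so the optimal action
values can be computed exactly by value iteration and used as ground
truth for the function-approximating agent.  A tabular TD(0) Q-learner
is included to verify that sampled one-step bootstrapping converges to
the same fixed point.

The oracle treats the MDP as infinite-horizon discounted (gamma < 1
keeps values finite; there are no terminal states, and the 20-step
episode horizon is a rollout cap, not an MDP property).  In particular
the optimal value of staying on a lesion block is the geometric series
1 / (1 - gamma).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .env import Action, GridSpec, LesionImage, build_grid, initial_state, step

__all__ = [
    "TabularMDP",
    "enumerate_mdp",
    "value_iteration",
    "tabular_q_learning",
    "greedy_policy",
    "optimal_path",
    "harmonic_lr",
    "polynomial_lr",
    "constant_lr",
]

N_ACTIONS = 3


@dataclass(frozen=True)
class TabularMDP:
    """Dense transition/reward tables over all (block, action) pairs.

    States are flat indices ``row * n_cols + col``.
    """

    grid: GridSpec
    transitions: np.ndarray  # (S, 3) int, next flat state
    rewards: np.ndarray      # (S, 3) float

    @property
    def n_states(self) -> int:
        return self.grid.n_blocks

    def state_index(self, row: int, col: int) -> int:
        return row * self.grid.n_cols + col

    def block_of(self, s: int) -> tuple[int, int]:
        return divmod(s, self.grid.n_cols)


def enumerate_mdp(image: LesionImage, grid: GridSpec | None = None) -> TabularMDP:
    """Build the tables by exhaustively calling the environment's step."""
    if grid is None:
        grid = build_grid(image)
    n = grid.n_blocks
    trans = np.zeros((n, N_ACTIONS), dtype=np.int64)
    rew = np.zeros((n, N_ACTIONS), dtype=np.float64)
    start = initial_state(image, grid.block_size)
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            state = type(start)(image=image, grid=grid, row=row, col=col)
            s = row * grid.n_cols + col
            for a in Action:
                out = step(state, a)
                trans[s, a.index] = out.next_state.row * grid.n_cols + out.next_state.col
                rew[s, a.index] = out.reward
    return TabularMDP(grid=grid, transitions=trans, rewards=rew)


def value_iteration(mdp: TabularMDP, gamma: float = 0.99,
                    tol: float = 1e-8, max_iter: int = 1_000_000) -> np.ndarray:
    """Q* via synchronous Bellman backups to sup-norm change < tol."""
    if not 0.0 <= gamma < 1.0:
        raise ValueError("gamma must lie in [0, 1)")
    if tol <= 0:
        raise ValueError("tol must be positive")
    q = np.zeros_like(mdp.rewards)
    for _ in range(max_iter):
        v_next = q.max(axis=1)[mdp.transitions]          # (S, 3)
        q_new = mdp.rewards + gamma * v_next
        if np.abs(q_new - q).max() < tol:
            return q_new
        q = q_new
    raise RuntimeError("value iteration did not converge within max_iter")


# learning-rate schedules: visit count (1-based) -> step size
def harmonic_lr(n: int) -> float:
    return 1.0 / n


def polynomial_lr(omega: float = 0.6) -> Callable[[int], float]:
    def lr(n: int) -> float:
        return 1.0 / n**omega
    return lr


def constant_lr(c: float = 1.0) -> Callable[[int], float]:
    return lambda n: c


def tabular_q_learning(mdp: TabularMDP, episodes: int, steps: int = 20,
                       lr_schedule: Callable[[int], float] = harmonic_lr,
                       epsilon: float = 1.0, gamma: float = 0.99,
                       rng: np.random.Generator | None = None) -> np.ndarray:
    """TD(0) Q-learning on the tabular MDP, episodes starting at (0, 0).

    Per-pair learning rates: the n-th update of a (state, action) pair
    uses ``lr_schedule(n)``.  ``epsilon`` = 1 gives pure exploration.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    q = np.zeros_like(mdp.rewards)
    visits = np.zeros_like(mdp.rewards, dtype=np.int64)
    trans, rew = mdp.transitions, mdp.rewards
    for _ in range(episodes):
        s = 0
        for _ in range(steps):
            if rng.random() < epsilon:
                a = int(rng.integers(N_ACTIONS))
            else:
                a = int(np.argmax(q[s]))
            s2 = trans[s, a]
            visits[s, a] += 1
            lr = lr_schedule(int(visits[s, a]))
            q[s, a] += lr * (rew[s, a] + gamma * q[s2].max() - q[s, a])
            s = s2
    return q


def greedy_policy(q: np.ndarray) -> np.ndarray:
    """Argmax action index per state, ties toward the lowest code."""
    return q.argmax(axis=1)


def optimal_path(q: np.ndarray, mdp: TabularMDP, start: tuple[int, int] = (0, 0),
                 max_steps: int = 100) -> list[tuple[int, int]]:
    """Follow argmax actions until the state repeats under STAY (or a cap)."""
    s = mdp.state_index(*start)
    path = [mdp.block_of(s)]
    for _ in range(max_steps):
        a = int(np.argmax(q[s]))
        s2 = int(mdp.transitions[s, a])
        if s2 == s and a == Action.STAY.index:
            break
        path.append(mdp.block_of(s2))
        if s2 == s:
            break  # clipped move loop; no further progress possible
        s = s2
    return path
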