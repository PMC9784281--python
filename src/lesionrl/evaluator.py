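"""Deployment rollouts, TP/FP scoring, and learning-curve comparison.

Deployment is strictly greedy: from the top-left block the agent takes
the argmax action for a fixed number of steps (20 by default).  A
rollout is a true positive (TP) when the final block has nonzero overlap
with the lesion mask and a false positive (FP) otherwise; with negatives
defined as zero for this localization task, accuracy = TP / (TP + FP).

Also provides the exact final-block distribution of a uniformly random
policy (dynamic programming over step counts), used as a chance floor
for the learned agent.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy import stats

from .dqn import encode_batch, greedy_action, q_forward
from .env import AgentState, GridSpec, LesionImage, block_overlap, initial_state, step
from .nn import ConvNet

__all__ = [
    "Outcome",
    "EvalOutcome",
    "EvalSummary",
    "greedy_rollout",
    "classify_outcome",
    "accuracy",
    "evaluate",
    "CurveComparison",
    "compare_curves",
    "random_walk_final_distribution",
    "random_policy_accuracy",
]


class Outcome(str, Enum):
    TP = "TP"
    FP = "FP"


@dataclass(frozen=True)
class EvalOutcome:
    image_id: str
    trajectory: tuple[tuple[int, int], ...]
    outcome: Outcome


@dataclass(frozen=True)
class EvalSummary:
    tp: int
    fp: int

    @property
    def n(self) -> int:
        return self.tp + self.fp

    @property
    def accuracy(self) -> float:
        return accuracy(self.tp, self.fp)


def greedy_rollout(net: ConvNet, image: LesionImage, n_steps: int = 20,
                   block_size: int = 60) -> list[AgentState]:
    """Argmax rollout from the top-left block; returns n_steps + 1 states."""
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    state = initial_state(image, block_size)
    states = [state]
    for _ in range(n_steps):
        q = q_forward(net, encode_batch([state]))
        state = step(state, greedy_action(q[0])).next_state
        states.append(state)
    return states


def classify_outcome(final_state: AgentState) -> Outcome:
    """TP iff the final block overlaps the lesion."""
    hit = block_overlap(final_state.image, final_state.row, final_state.col,
                        final_state.grid)
    return Outcome.TP if hit else Outcome.FP


def accuracy(tp: int, fp: int) -> float:
    """TP / (TP + FP); negatives are zero by definition for localization."""
    if tp < 0 or fp < 0:
        raise ValueError("counts must be non-negative")
    if tp + fp == 0:
        raise ValueError("accuracy undefined for tp + fp = 0")
    return tp / (tp + fp)


def evaluate(net: ConvNet, images: list[LesionImage], n_steps: int = 20,
             block_size: int = 60) -> tuple[EvalSummary, list[EvalOutcome]]:
    """Greedy rollout on every image, advanced in lock-step batches."""
    if not images:
        raise ValueError("images must be nonempty")
    states = [initial_state(img, block_size) for img in images]
    trajectories = [[s.block] for s in states]
    for _ in range(n_steps):
        q = net.forward(encode_batch(states))
        for i, s in enumerate(states):
            states[i] = step(s, greedy_action(q[i])).next_state
            trajectories[i].append(states[i].block)
    outcomes = [
        EvalOutcome(image_id=img.id, trajectory=tuple(traj),
                    outcome=classify_outcome(s))
        for img, traj, s in zip(images, trajectories, states)
    ]
    tp = sum(o.outcome is Outcome.TP for o in outcomes)
    return EvalSummary(tp=tp, fp=len(outcomes) - tp), outcomes


def outcomes_to_frame(outcomes: list[EvalOutcome]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "id": [o.image_id for o in outcomes],
            "outcome": [o.outcome.value for o in outcomes],
            "final_row": [o.trajectory[-1][0] for o in outcomes],
            "final_col": [o.trajectory[-1][1] for o in outcomes],
            "trajectory": [
                "->".join(f"({r},{c})" for r, c in o.trajectory) for o in outcomes
            ],
        }
    )


@dataclass(frozen=True)
class CurveComparison:
    mean_a: float
    mean_b: float
    difference: float
    p_value: float


def compare_curves(curve_a, curve_b, window: int = 20) -> CurveComparison:
    """Compare the tails of two learning curves.

    Means over the final ``window`` accuracies of each curve, their
    difference (a - b), and a Welch two-sample t-test p-value on those
    windows.  Curves are sequences of (episode, accuracy) pairs or plain
    accuracy sequences.
    """
    a = _tail_accuracies(curve_a, window)
    b = _tail_accuracies(curve_b, window)
    mean_a, mean_b = float(a.mean()), float(b.mean())
    if np.allclose(a, a[0]) and np.allclose(b, b[0]):
        p = 1.0 if np.isclose(mean_a, mean_b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    return CurveComparison(mean_a=mean_a, mean_b=mean_b,
                           difference=mean_a - mean_b, p_value=p)


def _tail_accuracies(curve, window: int) -> np.ndarray:
    arr = np.asarray(curve, dtype=float)
    if arr.ndim == 2:
        arr = arr[:, 1]
    if window < 1 or window > arr.shape[0]:
        raise ValueError(f"window {window} exceeds curve length {arr.shape[0]}")
    return arr[-window:]


def random_walk_final_distribution(grid: GridSpec, n_steps: int) -> np.ndarray:
    """Exact block-occupancy distribution of a uniform random policy.

    Dynamic programming over steps: from each block the walk stays, moves
    down, or moves right with probability 1/3 each, with off-grid moves
    clipped.  Returns an (n_rows, n_cols) array summing to 1.
    """
    p = np.zeros((grid.n_rows, grid.n_cols))
    p[0, 0] = 1.0
    for _ in range(n_steps):
        q = p / 3.0
        nxt = q.copy()                      # stay
        nxt[1:, :] += q[:-1, :]             # down
        nxt[-1, :] += q[-1, :]              # down clipped at last row
        nxt[:, 1:] += q[:, :-1]             # right
        nxt[:, -1] += q[:, -1]              # right clipped at last column
        p = nxt
    return p


def random_policy_accuracy(images: list[LesionImage], n_steps: int = 20,
                           block_size: int = 60) -> float:
    """Expected TP fraction of a uniformly random policy, computed exactly."""
    if not images:
        raise ValueError("images must be nonempty")
    total = 0.0
    for img in images:
        grid = GridSpec(*img.shape, block_size)
        dist = random_walk_final_distribution(grid, n_steps)
        hit = np.array(
            [
                [block_overlap(img, r, c, grid) for c in range(grid.n_cols)]
                for r in range(grid.n_rows)
            ]
        )
        total += float(dist[hit].sum())
    return total / len(images)
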