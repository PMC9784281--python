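"""Training orchestration: episodes, replay, logging, cross-validation.

Each episode samples one training image (uniformly with replacement),
starts the agent in the top-left block, and runs a fixed number of
environment steps (20).  Every step stores a transition in the replay
buffer and — once the buffer holds at least one batch — performs one
Adam step on the TD(0) L1 loss.  After each ``eval_every`` episodes the
greedy test-set accuracy is appended to the learning curve.

A single master seed fans out to independent streams for weight
initialization, image sampling, exploration, and batch sampling, making
runs bit-reproducible for a fixed thread count.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dqn import (
    Adam,
    EpsilonSchedule,
    ReplayBuffer,
    Transition,
    build_q_network,
    encode_batch,
    epsilon_at,
    q_forward,
    select_action,
    train_batch,
)
from .env import LesionImage, initial_state, step
from .evaluator import evaluate
from .nn import ConvNet

__all__ = [
    "TrainConfig",
    "EpisodeLog",
    "TrainResult",
    "run_episode",
    "train",
    "crossvalidate",
    "run_synthetic_experiment",
]


@dataclass(frozen=True)
class TrainConfig:
    """All training hyperparameters, defaulting to the study protocol."""

    n_episodes: int = 90
    steps_per_episode: int = 20
    gamma: float = 0.99
    batch_size: int = 128
    buffer_capacity: int = 15_000
    learning_rate: float = 1e-4
    epsilon: EpsilonSchedule = field(default_factory=EpsilonSchedule)
    block_size: int = 60
    seed: int = 0
    eval_every: int = 1
    hidden_sizes: tuple[int, ...] = (512, 128)

    def __post_init__(self) -> None:
        for name in ("n_episodes", "steps_per_episode", "batch_size",
                     "buffer_capacity", "block_size", "eval_every"):
            if getattr(self, name) < (0 if name == "n_episodes" else 1):
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.gamma < 1.0:
            raise ValueError("gamma must lie in [0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "TrainConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        eps_raw = raw.pop("epsilon", None)
        eps = EpsilonSchedule(**eps_raw) if eps_raw else EpsilonSchedule()
        if "hidden_sizes" in raw:
            raw["hidden_sizes"] = tuple(raw["hidden_sizes"])
        return cls(epsilon=eps, **raw)

    def to_yaml(self, path: str | Path) -> None:
        d = {
            k: getattr(self, k)
            for k in ("n_episodes", "steps_per_episode", "gamma", "batch_size",
                      "buffer_capacity", "learning_rate", "block_size", "seed",
                      "eval_every")
        }
        d["hidden_sizes"] = list(self.hidden_sizes)
        d["epsilon"] = {
            "epsilon_initial": self.epsilon.epsilon_initial,
            "decay_per_episode": self.epsilon.decay_per_episode,
            "epsilon_min": self.epsilon.epsilon_min,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


@dataclass(frozen=True)
class EpisodeLog:
    episode: int
    image_id: str
    epsilon: float
    rewards: tuple[float, ...]
    losses: tuple[float, ...]

    @property
    def cumulative_reward(self) -> float:
        return float(sum(self.rewards))


@dataclass
class TrainResult:
    net: ConvNet
    curve: list[tuple[int, float]]
    logs: list[EpisodeLog]

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve, columns=["episode", "accuracy"])

    def log_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "episode": [l.episode for l in self.logs],
                "image_id": [l.image_id for l in self.logs],
                "epsilon": [l.epsilon for l in self.logs],
                "cumulative_reward": [l.cumulative_reward for l in self.logs],
                "mean_loss": [
                    float(np.mean(l.losses)) if l.losses else np.nan
                    for l in self.logs
                ],
            }
        )


def run_episode(net: ConvNet, optimizer: Adam, image: LesionImage,
                buffer: ReplayBuffer, epsilon: float, config: TrainConfig,
                explore_rng: np.random.Generator,
                batch_rng: np.random.Generator,
                episode_index: int = 0) -> EpisodeLog:
    """One training episode: act, store, and (when warm) learn each step."""
    state = initial_state(image, config.block_size)
    rewards: list[float] = []
    losses: list[float] = []
    for _ in range(config.steps_per_episode):
        q = q_forward(net, encode_batch([state]))[0]
        action = select_action(q, epsilon, explore_rng)
        outcome = step(state, action)
        buffer.push(Transition(state=state, action=action,
                               reward=outcome.reward,
                               next_state=outcome.next_state))
        rewards.append(outcome.reward)
        state = outcome.next_state
        if len(buffer) >= config.batch_size:
            batch = buffer.sample(config.batch_size, batch_rng)
            losses.append(train_batch(net, optimizer, batch, config.gamma))
    return EpisodeLog(episode=episode_index, image_id=image.id, epsilon=epsilon,
                      rewards=tuple(rewards), losses=tuple(losses))


def train(train_images: list[LesionImage], test_images: list[LesionImage],
          config: TrainConfig) -> TrainResult:
    """Full training run with periodic greedy evaluation on the test set."""
    if not train_images:
        raise ValueError("training image list is empty")
    h, w = train_images[0].shape
    ss = np.random.SeedSequence(config.seed)
    seed_weights, seed_images, seed_explore, seed_batch = ss.spawn(4)
    net = build_q_network(h, w, seed=seed_weights,
                          hidden_sizes=config.hidden_sizes)
    optimizer = Adam(net, lr=config.learning_rate)
    buffer = ReplayBuffer(config.buffer_capacity)
    image_rng = np.random.default_rng(seed_images)
    explore_rng = np.random.default_rng(seed_explore)
    batch_rng = np.random.default_rng(seed_batch)

    curve: list[tuple[int, float]] = []
    logs: list[EpisodeLog] = []
    for episode in range(config.n_episodes):
        image = train_images[int(image_rng.integers(len(train_images)))]
        eps = epsilon_at(config.epsilon, episode)
        logs.append(run_episode(net, optimizer, image, buffer, eps, config,
                                explore_rng, batch_rng, episode_index=episode))
        if test_images and (episode + 1) % config.eval_every == 0:
            summary, _ = evaluate(net, test_images,
                                  n_steps=config.steps_per_episode,
                                  block_size=config.block_size)
            curve.append((episode, summary.accuracy))
    return TrainResult(net=net, curve=curve, logs=logs)


def crossvalidate(set_a: list[LesionImage], set_b: list[LesionImage],
                  config: TrainConfig) -> tuple[float, float, float]:
    """Twofold cross-validation: train on A test on B, then reversed.

    Each fold trains from scratch with a fresh seed derived from the
    config seed.  Returns (accuracy on B, accuracy on A, mean).
    """
    if not set_a or not set_b:
        raise ValueError("both folds must be nonempty")
    fold_seeds = np.random.SeedSequence(config.seed).spawn(2)
    accs = []
    for (tr, te), fs in zip(((set_a, set_b), (set_b, set_a)), fold_seeds):
        fold_cfg = replace(config, seed=int(fs.generate_state(1)[0] % (2**31)))
        result = train(tr, te, fold_cfg)
        summary, _ = evaluate(result.net, te, n_steps=config.steps_per_episode,
                              block_size=config.block_size)
        accs.append(summary.accuracy)
    return accs[0], accs[1], float(np.mean(accs))


def run_synthetic_experiment(seed: int, n_train: int = 30, n_test: int = 30,
                             image_size: int = 32,
                             config: TrainConfig | None = None):
    """The study protocol on phantoms: 30/30 split, 90 episodes.

    Phantoms are drawn at ``image_size`` pixels with a 4x4 block grid
    (the packaged experiment runs at 32 px so a full protocol finishes in
    minutes on one core; the MDP — 16 blocks, 3 actions, 20 steps — is
    identical at every resolution).  Returns the TrainResult, the test
    images, and the exact random-policy accuracy on the same test set.
    """
    from .evaluator import random_policy_accuracy
    from .phantom import PhantomConfig, generate_dataset

    block_size = image_size // 4
    pc = PhantomConfig(image_size=image_size)
    ss = np.random.SeedSequence(seed)
    s_train, s_test, s_run = (int(s.generate_state(1)[0] % (2**31))
                              for s in ss.spawn(3))
    train_images = generate_dataset(n_train, pc, seed=s_train)
    test_images = generate_dataset(n_test, pc, seed=s_test)
    if config is None:
        config = TrainConfig(block_size=block_size, seed=s_run)
    else:
        config = replace(config, block_size=block_size, seed=s_run)
    result = train(train_images, test_images, config)
    chance = random_policy_accuracy(test_images,
                                    n_steps=config.steps_per_episode,
                                    block_size=block_size)
    return result, test_images, chance
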