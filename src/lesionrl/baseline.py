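"""Supervised keypoint-regression baseline.

A CNN with a trunk identical to the Q-network's regresses the lesion
centroid, normalized to [0, 1] per axis.  Training minimizes the mean
absolute coordinate error with Adam over full-dataset passes (one epoch
= one pass).  A prediction counts as a true positive when the predicted
pixel falls on the lesion mask, a false positive otherwise, scored with
the same TP / (TP + FP) statistic as the reinforcement-learning agent.

The network consumes the same two-channel observation layout as the
agent with the agent-position channel all zero, keeping the trunks
exactly parameter-for-parameter comparable.
"""

from __future__ import annotations

import numpy as np

from .env import LesionImage
from .evaluator import EvalSummary
from .nn import Adam, ConvNet, ConvNetSpec

__all__ = [
    "keypoint_network_spec",
    "build_keypoint_network",
    "lesion_centroid",
    "train_keypoint",
    "evaluate_keypoint",
]


def keypoint_network_spec(height: int = 240, width: int = 240,
                          hidden_sizes: tuple[int, ...] = (512, 128)) -> ConvNetSpec:
    return ConvNetSpec(input_channels=2, input_height=height, input_width=width,
                       conv_channels=32, n_conv_layers=4,
                       hidden_sizes=hidden_sizes, output_size=2)


def build_keypoint_network(height: int = 240, width: int = 240,
                           seed: int | np.random.SeedSequence = 0,
                           hidden_sizes: tuple[int, ...] = (512, 128)) -> ConvNet:
    return ConvNet(keypoint_network_spec(height, width, hidden_sizes), seed=seed)


def lesion_centroid(mask: np.ndarray) -> tuple[float, float]:
    """Arithmetic mean (row, col) of the positive mask pixels."""
    mask = np.asarray(mask) != 0
    if not mask.any():
        raise ValueError("mask has no positive pixel")
    rows, cols = np.nonzero(mask)
    return float(rows.mean()), float(cols.mean())


def _inputs_and_targets(images: list[LesionImage]) -> tuple[np.ndarray, np.ndarray]:
    h, w = images[0].shape
    x = np.zeros((len(images), 2, h, w), dtype=np.float32)
    y = np.zeros((len(images), 2), dtype=np.float32)
    for i, img in enumerate(images):
        x[i, 0] = img.intensities
        r, c = lesion_centroid(img.lesion_mask)
        y[i] = (r / (h - 1), c / (w - 1))
    return x, y


def train_keypoint(images: list[LesionImage], epochs: int = 90,
                   learning_rate: float = 1e-4,
                   seed: int | np.random.SeedSequence = 0,
                   eval_images: list[LesionImage] | None = None,
                   net: ConvNet | None = None):
    """Fit the keypoint CNN; optionally log a per-epoch test-accuracy curve.

    Returns ``(net, losses, curve)`` where ``losses`` holds the pre-step
    training loss per epoch and ``curve`` the (epoch, accuracy) pairs on
    ``eval_images`` (empty when none are given).
    """
    if not images:
        raise ValueError("image list is empty")
    h, w = images[0].shape
    if net is None:
        net = build_keypoint_network(h, w, seed=seed)
    optimizer = Adam(net, lr=learning_rate)
    x, y = _inputs_and_targets(images)
    losses: list[float] = []
    curve: list[tuple[int, float]] = []
    for epoch in range(epochs):
        pred = net.forward(x, keep_cache=True)
        residual = pred - y
        losses.append(float(np.abs(residual).mean()))
        dout = np.sign(residual).astype(np.float32) / residual.size
        optimizer.step(net.backward(dout))
        if eval_images:
            curve.append((epoch, evaluate_keypoint(net, eval_images)[0].accuracy))
    return net, losses, curve


def evaluate_keypoint(net: ConvNet, images: list[LesionImage]
                      ) -> tuple[EvalSummary, list[tuple[int, int]]]:
    """Score predictions: TP iff the predicted pixel lies on the lesion."""
    if not images:
        raise ValueError("image list is empty")
    h, w = images[0].shape
    x, _ = _inputs_and_targets(images)
    pred = net.forward(x)
    rows = np.clip(np.round(pred[:, 0] * (h - 1)), 0, h - 1).astype(int)
    cols = np.clip(np.round(pred[:, 1] * (w - 1)), 0, w - 1).astype(int)
    tp = 0
    points = []
    for img, r, c in zip(images, rows, cols):
        points.append((int(r), int(c)))
        tp += bool(img.lesion_mask[r, c])
    return EvalSummary(tp=tp, fp=len(images) - tp), points
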