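"""Minimal convolutional network core on numpy.

Implements exactly the family of architectures used here: a trunk of
stride-2 3x3 convolutions (32 channels each, ELU), a flatten, a stack of
fully connected ELU layers, and a linear output head.  Convolutions are
evaluated as an im2col matrix product so the heavy lifting is a single
BLAS call per layer; backward passes mirror that.  All arithmetic is
float32 and fully deterministic for a fixed seed and thread count.

This is deliberately small: no autograd, no graphs — just the forward
and backward passes of this one architecture plus an Adam optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import as_strided

__all__ = ["ConvNetSpec", "ConvNet", "Adam"]


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(x))


def _elu_grad(out: np.ndarray) -> np.ndarray:
    # ELU' expressed through the activation output: 1 where positive,
    # out + 1 (= exp(x)) on the negative branch.
    return np.where(out > 0, np.float32(1.0), out + np.float32(1.0))


def _out_hw(h: int, w: int) -> tuple[int, int]:
    # stride 2, kernel 3, pad 1: ceil(h / 2)
    return (h + 1) // 2, (w + 1) // 2


def _conv_cols(x: np.ndarray) -> np.ndarray:
    """im2col for a 3x3/stride-2/pad-1 convolution.

    Returns (N * Ho * Wo, C * 9) with patch channels varying slowest.
    """
    n, c, h, w = x.shape
    ho, wo = _out_hw(h, w)
    xp = np.zeros((n, c, h + 2, w + 2), dtype=x.dtype)
    xp[:, :, 1:-1, 1:-1] = x
    sn, sc, sh, sw = xp.strides
    patches = as_strided(
        xp,
        shape=(n, ho, wo, c, 3, 3),
        strides=(sn, 2 * sh, 2 * sw, sc, sh, sw),
        writeable=False,
    )
    return np.ascontiguousarray(patches).reshape(n * ho * wo, c * 9)


@dataclass(frozen=True)
class ConvNetSpec:
    """Architecture hyperparameters.

    The defaults are the localization network: 4 stride-2 conv layers of
    32 channels on a 2-channel input, then 512- and 128-unit ELU layers,
    then a linear head (3 Q-values, or 2 keypoint coordinates).
    """

    input_channels: int = 2
    input_height: int = 240
    input_width: int = 240
    conv_channels: int = 32
    n_conv_layers: int = 4
    hidden_sizes: tuple[int, ...] = (512, 128)
    output_size: int = 3

    def conv_shapes(self) -> list[tuple[int, int, int]]:
        """(channels, height, width) after each conv layer."""
        shapes = []
        h, w = self.input_height, self.input_width
        for _ in range(self.n_conv_layers):
            h, w = _out_hw(h, w)
            shapes.append((self.conv_channels, h, w))
        return shapes

    @property
    def flat_size(self) -> int:
        c, h, w = self.conv_shapes()[-1]
        return c * h * w


class ConvNet:
    """Forward/backward evaluation of a ConvNetSpec with explicit parameters."""

    def __init__(self, spec: ConvNetSpec, seed: int | np.random.SeedSequence = 0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        self.conv_w: list[np.ndarray] = []
        self.conv_b: list[np.ndarray] = []
        c_in = spec.input_channels
        for _ in range(spec.n_conv_layers):
            fan_in = c_in * 9
            w = rng.normal(0.0, np.sqrt(2.0 / fan_in),
                           size=(spec.conv_channels, c_in, 3, 3)).astype(np.float32)
            self.conv_w.append(w)
            self.conv_b.append(np.zeros(spec.conv_channels, dtype=np.float32))
            c_in = spec.conv_channels
        self.fc_w: list[np.ndarray] = []
        self.fc_b: list[np.ndarray] = []
        sizes = (spec.flat_size,) + spec.hidden_sizes + (spec.output_size,)
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(np.float32)
            self.fc_w.append(w)
            self.fc_b.append(np.zeros(n_out, dtype=np.float32))
        self._cache: dict | None = None

    # -- parameter bookkeeping -------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.conv_w + self.conv_b + self.fc_w + self.fc_b

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def trunk_parameter_count(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.conv_w, self.conv_b))

    def state_dict(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        for i, (w, b) in enumerate(zip(self.conv_w, self.conv_b)):
            d[f"conv{i}.w"], d[f"conv{i}.b"] = w, b
        for i, (w, b) in enumerate(zip(self.fc_w, self.fc_b)):
            d[f"fc{i}.w"], d[f"fc{i}.b"] = w, b
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for i in range(len(self.conv_w)):
            self.conv_w[i] = np.asarray(d[f"conv{i}.w"], dtype=np.float32)
            self.conv_b[i] = np.asarray(d[f"conv{i}.b"], dtype=np.float32)
        for i in range(len(self.fc_w)):
            self.fc_w[i] = np.asarray(d[f"fc{i}.w"], dtype=np.float32)
            self.fc_b[i] = np.asarray(d[f"fc{i}.b"], dtype=np.float32)

    def save(self, path) -> None:
        np.savez(path, **self.state_dict())

    @classmethod
    def load(cls, path, spec: ConvNetSpec) -> "ConvNet":
        net = cls(spec, seed=0)
        with np.load(path) as d:
            net.load_state_dict(dict(d))
        return net

    # -- forward / backward ----------------------------------------------------

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        """Batched forward pass: (N, C, H, W) -> (N, output_size)."""
        spec = self.spec
        x = np.asarray(x, dtype=np.float32)
        if x.ndim != 4 or x.shape[1:] != (spec.input_channels, spec.input_height,
                                          spec.input_width):
            raise ValueError(
                f"expected input of shape (N, {spec.input_channels}, "
                f"{spec.input_height}, {spec.input_width}), got {x.shape}"
            )
        n = x.shape[0]
        conv_cols: list[np.ndarray] = []
        conv_out: list[np.ndarray] = []
        cur = x
        for w, b in zip(self.conv_w, self.conv_b):
            ho, wo = _out_hw(cur.shape[2], cur.shape[3])
            cols = _conv_cols(cur)
            out = cols @ w.reshape(w.shape[0], -1).T + b
            out = _elu(out)
            conv_cols.append(cols)
            conv_out.append(out)  # (N*Ho*Wo, C_out)
            cur = out.reshape(n, ho, wo, w.shape[0]).transpose(0, 3, 1, 2)
        flat = cur.reshape(n, -1)
        fc_in: list[np.ndarray] = []
        fc_out: list[np.ndarray] = []
        h = flat
        for i, (w, b) in enumerate(zip(self.fc_w, self.fc_b)):
            fc_in.append(h)
            z = h @ w + b
            h = z if i == len(self.fc_w) - 1 else _elu(z)
            fc_out.append(h)
        if keep_cache:
            self._cache = {
                "x_shape": x.shape,
                "conv_cols": conv_cols,
                "conv_out": conv_out,
                "fc_in": fc_in,
                "fc_out": fc_out,
            }
        return h

    def backward(self, dout: np.ndarray) -> list[np.ndarray]:
        """Gradients of the cached forward pass w.r.t. all parameters.

        ``dout`` is dLoss/dOutput, shape (N, output_size).  Returns grads
        ordered as :meth:`parameters`.
        """
        if self._cache is None:
            raise RuntimeError("backward() requires a forward(..., keep_cache=True)")
        cache = self._cache
        n = cache["x_shape"][0]
        spec = self.spec

        d_fc_w: list[np.ndarray] = [None] * len(self.fc_w)
        d_fc_b: list[np.ndarray] = [None] * len(self.fc_b)
        grad = np.asarray(dout, dtype=np.float32)
        for i in range(len(self.fc_w) - 1, -1, -1):
            if i != len(self.fc_w) - 1:
                grad = grad * _elu_grad(cache["fc_out"][i])
            d_fc_w[i] = cache["fc_in"][i].T @ grad
            d_fc_b[i] = grad.sum(axis=0)
            grad = grad @ self.fc_w[i].T

        # reshape flat gradient back to the last conv output layout
        c, h, w = spec.conv_shapes()[-1]
        grad = grad.reshape(n, c, h, w)

        d_conv_w: list[np.ndarray] = [None] * len(self.conv_w)
        d_conv_b: list[np.ndarray] = [None] * len(self.conv_b)
        in_shapes = [(spec.input_channels, spec.input_height, spec.input_width)]
        in_shapes += spec.conv_shapes()[:-1]
        for i in range(len(self.conv_w) - 1, -1, -1):
            c_out, ho, wo = spec.conv_shapes()[i]
            g = grad.transpose(0, 2, 3, 1).reshape(n * ho * wo, c_out)
            g = g * _elu_grad(cache["conv_out"][i])
            wmat = self.conv_w[i].reshape(c_out, -1)
            d_conv_w[i] = (g.T @ cache["conv_cols"][i]).reshape(self.conv_w[i].shape)
            d_conv_b[i] = g.sum(axis=0)
            if i == 0:
                break  # input gradient not needed
            c_in, hi, wi = in_shapes[i]
            dcols = g @ wmat  # (N*Ho*Wo, C_in*9)
            dpatch = dcols.reshape(n, ho, wo, c_in, 3, 3).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros((n, c_in, hi + 2, wi + 2), dtype=np.float32)
            for ki in range(3):
                for kj in range(3):
                    dxp[:, :, ki:ki + 2 * ho:2, kj:kj + 2 * wo:2] += dpatch[..., ki, kj]
            grad = dxp[:, :, 1:-1, 1:-1]
        self._cache = None
        return d_conv_w + d_conv_b + d_fc_w + d_fc_b


class Adam:
    """Adam optimizer over a ConvNet's parameter list."""

    def __init__(self, net: ConvNet, lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        params = net.parameters()
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self.t
        bias2 = 1.0 - b2 ** self.t
        for p, g, m, v in zip(self.net.parameters(), grads, self.m, self.v):
            g = g.astype(np.float32)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
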