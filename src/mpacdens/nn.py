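"""Small dense neural networks with hand-written reverse-mode gradients.

Architectures here are tiny (3x16 or 4x64), training batches are whole
systems, and determinism matters more than throughput, so the forward and
backward passes are written directly in numpy.  Adam with a linear warm-up
followed by exponential decay reproduces the training schedule of the
functional models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLPSpec", "MLP", "Adam", "lr_schedule"]


@dataclass(frozen=True)
class MLPSpec:
    """Architecture of a weight-producing network.

    output activation 'tanh' bounds outputs in [-scale, scale];
    'sigmoid' in [0, scale].
    """

    n_inputs: int
    hidden: tuple[int, ...] = (16, 16, 16)
    output_activation: str = "tanh"  # or "sigmoid"
    n_outputs: int = 1
    output_scale: float = 1.0

    @staticmethod
    def ml2(n_inputs: int = 5) -> "MLPSpec":
        return MLPSpec(n_inputs=n_inputs, hidden=(16, 16, 16),
                       output_activation="tanh", n_outputs=1, output_scale=1.0)

    @staticmethod
    def mls2(n_inputs: int = 8) -> "MLPSpec":
        return MLPSpec(n_inputs=n_inputs, hidden=(64, 64, 64, 64),
                       output_activation="sigmoid", n_outputs=2, output_scale=10.0)


def _act(name: str, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Activation value and derivative."""
    if name == "tanh":
        a = np.tanh(z)
        return a, 1.0 - a * a
    if name == "sigmoid":
        a = 1.0 / (1.0 + np.exp(-np.clip(z, -500, 500)))
        return a, a * (1.0 - a)
    raise ValueError(f"unknown activation '{name}'")


class MLP:
    """Fully connected network, tanh hidden layers."""

    def __init__(self, spec: MLPSpec, rng: np.random.Generator):
        self.spec = spec
        sizes = [spec.n_inputs, *spec.hidden, spec.n_outputs]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-bound, bound, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- parameter vector interface --
    def get_flat(self) -> np.ndarray:
        return np.concatenate(
            [w.ravel() for w in self.weights] + [b.ravel() for b in self.biases]
        )

    def set_flat(self, x: np.ndarray) -> None:
        off = 0
        for i, w in enumerate(self.weights):
            self.weights[i] = x[off : off + w.size].reshape(w.shape)
            off += w.size
        for i, b in enumerate(self.biases):
            self.biases[i] = x[off : off + b.size].reshape(b.shape)
            off += b.size

    def force_constant_output(self, y: float) -> "MLP":
        """Zero all weights and set the output bias so the net emits y.

        Handy for identity/zero-weight limits (e.g. recovering plain
        regularized MP2 from the spin-scaled model).
        """
        for i in range(len(self.weights)):
            self.weights[i] = np.zeros_like(self.weights[i])
            self.biases[i] = np.zeros_like(self.biases[i])
        target = y / self.spec.output_scale
        if self.spec.output_activation == "tanh":
            z = np.arctanh(np.clip(target, -1 + 1e-16, 1 - 1e-16))
        else:  # sigmoid
            z = -np.log(1.0 / np.clip(target, 1e-300, 1 - 1e-16) - 1.0)
        self.biases[-1] = np.full(self.spec.n_outputs, z)
        return self

    def forward(self, X: np.ndarray, need_cache: bool = False):
        a = X
        cache = [("input", X, None)]
        n_hidden = len(self.weights) - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ w + b
            name = "tanh" if i < n_hidden else self.spec.output_activation
            a, da = _act(name, z)
            cache.append(("layer", a, da))
        out = self.spec.output_scale * a
        if need_cache:
            return out, cache
        return out

    def backward(self, cache, dout: np.ndarray) -> np.ndarray:
        """Gradient of sum(dout * output) w.r.t. the flat parameter vector."""
        grads_w = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        delta = dout * self.spec.output_scale
        for i in range(len(self.weights) - 1, -1, -1):
            _, a_out, da = cache[i + 1]
            delta = delta * da
            a_in = cache[i][1]
            grads_w[i] = a_in.T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.weights[i].T
        return np.concatenate(
            [g.ravel() for g in grads_w] + [g.ravel() for g in grads_b]
        )


def lr_schedule(
    epoch: int, n_epochs: int, base_lr: float, warmup_frac: float, decay_to: float
) -> float:
    """Linear warm-up to base_lr, then exponential decay to decay_to*base_lr."""
    n_warm = max(1, int(round(warmup_frac * n_epochs)))
    if epoch < n_warm:
        return base_lr * (epoch + 1) / n_warm
    frac = (epoch - n_warm) / max(1, n_epochs - n_warm)
    return base_lr * decay_to ** frac


@dataclass
class Adam:
    n_params: int
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    m: np.ndarray = field(init=False)
    v: np.ndarray = field(init=False)
    t: int = field(init=False, default=0)

    def __post_init__(self):
        self.m = np.zeros(self.n_params)
        self.v = np.zeros(self.n_params)

    def step(self, params: np.ndarray, grad: np.ndarray, lr: float) -> np.ndarray:
        self.t += 1
        self.m = self.beta1 * self.m + (1 - self.beta1) * grad
        self.v = self.beta2 * self.v + (1 - self.beta2) * grad * grad
        mhat = self.m / (1 - self.beta1 ** self.t)
        vhat = self.v / (1 - self.beta2 ** self.t)
        return params - lr * mhat / (np.sqrt(vhat) + self.eps)
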