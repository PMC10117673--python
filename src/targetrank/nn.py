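"""A compact, fully seeded dense network for binary classification.

Architecture: input -> dense(64, tanh) -> dense(32, tanh) -> dense(1,
sigmoid), trained with binary cross-entropy plus L2 penalties on the hidden
layers' weights and biases, optimized with Nadam (Adam with Nesterov
momentum).  Everything — weight initialization and the per-epoch shuffle —
is driven by one NumPy generator, so training is bit-reproducible given the
seed.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np

_EPS = 1e-12


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class NadamOptimizer:
    """Nadam: Adam with a Nesterov-style lookahead on the first moment."""

    def __init__(self, learning_rate=0.002, beta1=0.9, beta2=0.999, epsilon=1e-7):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.epsilon = epsilon
        self.t = 0
        self._m: list[np.ndarray] | None = None
        self._v: list[np.ndarray] | None = None

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if self._m is None:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self.t += 1
        b1, b2, t = self.beta1, self.beta2, self.t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            # Nesterov lookahead: blend the bias-corrected first moment with
            # the current gradient's bias-corrected contribution.
            m_hat = m / (1 - b1 ** (t + 1))
            g_hat = g / (1 - b1**t)
            v_hat = v / (1 - b2**t)
            p -= self.lr * (b1 * m_hat + (1 - b1) * g_hat) / (np.sqrt(v_hat) + self.epsilon)


class DenseNetwork:
    """Feed-forward binary classifier with tanh hidden layers.

    Parameters
    ----------
    input_dim : width of the feature vectors.
    hidden_sizes : widths of the hidden layers (default (64, 32)).
    l2 : L2 penalty applied to both weights and biases of the hidden layers.
    init_scale : std of the zero-mean Gaussian weight initialization.
    seed : drives initialization and the minibatch shuffle.
    """

    def __init__(
        self,
        input_dim: int,
        hidden_sizes: Sequence[int] = (64, 32),
        learning_rate: float = 0.01,
        batch_size: int = 16,
        epochs: int = 30,
        l2: float = 1e-3,
        init_scale: float = 0.05,
        seed: int = 0,
    ):
        self.input_dim = int(input_dim)
        self.hidden_sizes = tuple(int(h) for h in hidden_sizes)
        self.learning_rate = float(learning_rate)
        self.batch_size = int(batch_size)
        self.epochs = int(epochs)
        self.l2 = float(l2)
        self.init_scale = float(init_scale)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        sizes = (self.input_dim, *self.hidden_sizes, 1)
        self.weights = [
            rng.normal(0.0, self.init_scale, size=(sizes[i], sizes[i + 1]))
            for i in range(len(sizes) - 1)
        ]
        self.biases = [np.zeros(sizes[i + 1]) for i in range(len(sizes) - 1)]
        self._rng = rng
        self.loss_history: list[float] = []

    # -- forward / backward -------------------------------------------------

    def _forward(self, X: np.ndarray) -> list[np.ndarray]:
        activations = [X]
        a = X
        n_layers = len(self.weights)
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            z = a @ W + b
            a = _sigmoid(z) if i == n_layers - 1 else np.tanh(z)
            activations.append(a)
        return activations

    def _loss(self, p: np.ndarray, y: np.ndarray) -> float:
        p = np.clip(p, _EPS, 1 - _EPS)
        bce = -np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))
        # L2 on the hidden layers' kernels and biases only.
        reg = self.l2 * sum(
            float(np.sum(W**2) + np.sum(b**2))
            for W, b in zip(self.weights[:-1], self.biases[:-1])
        )
        return float(bce + reg)

    def _gradients(self, activations, y):
        n = y.shape[0]
        grads_W = [None] * len(self.weights)
        grads_b = [None] * len(self.biases)
        # sigmoid + BCE: dL/dz at the output is (p - y) / n
        delta = (activations[-1] - y[:, None]) / n
        for i in range(len(self.weights) - 1, -1, -1):
            grads_W[i] = activations[i].T @ delta
            grads_b[i] = delta.sum(axis=0)
            if i < len(self.weights) - 1:  # hidden layer: add L2 terms
                grads_W[i] += 2 * self.l2 * self.weights[i]
                grads_b[i] += 2 * self.l2 * self.biases[i]
            if i > 0:
                delta = (delta @ self.weights[i].T) * (1 - activations[i] ** 2)
        return grads_W, grads_b

    # -- public API ---------------------------------------------------------

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DenseNetwork":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=np.float64).ravel()
        if X.shape[0] != y.shape[0]:
            raise ValueError("X and y disagree on the number of samples")
        if X.shape[1] != self.input_dim:
            raise ValueError(
                f"expected {self.input_dim} features, got {X.shape[1]}"
            )
        opt = NadamOptimizer(learning_rate=self.learning_rate)
        n = X.shape[0]
        for _ in range(self.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                acts = self._forward(X[idx])
                gW, gb = self._gradients(acts, y[idx])
                opt.step(self.weights + self.biases, gW + gb)
            self.loss_history.append(self._loss(self._forward(X)[-1].ravel(), y))
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(
                f"model expects {self.input_dim}-dimensional input, "
                f"got shape {X.shape}"
            )
        return self._forward(X)[-1].ravel()

    @property
    def n_parameters(self) -> int:
        return sum(W.size for W in self.weights) + sum(b.size for b in self.biases)

    # -- persistence ----------------------------------------------------------

    def save(self, directory: Path | str) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        config = {
            "input_dim": self.input_dim,
            "hidden_sizes": list(self.hidden_sizes),
            "learning_rate": self.learning_rate,
            "batch_size": self.batch_size,
            "epochs": self.epochs,
            "l2": self.l2,
            "init_scale": self.init_scale,
            "seed": self.seed,
        }
        (directory / "config.json").write_text(json.dumps(config, indent=2))
        arrays = {}
        for i, (W, b) in enumerate(zip(self.weights, self.biases)):
            arrays[f"W{i}"] = W
            arrays[f"b{i}"] = b
        np.savez(directory / "parameters.npz", **arrays)

    @classmethod
    def load(cls, directory: Path | str) -> "DenseNetwork":
        directory = Path(directory)
        config = json.loads((directory / "config.json").read_text())
        model = cls(**config)
        with np.load(directory / "parameters.npz") as data:
            model.weights = [data[f"W{i}"] for i in range(len(model.weights))]
            model.biases = [data[f"b{i}"] for i in range(len(model.biases))]
        return model
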