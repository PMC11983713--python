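"""Dense feed-forward networks with Swish activations, in plain numpy.

The charge and charge-transfer predictors are small scalar-output networks
(four hidden layers).  Forces need the exact reverse-mode derivative of the
output with respect to the *inputs* (dq/dF), and training needs parameter
gradients; both are provided analytically.

The Swish activation A(x) = x·σ(βx) with β = 3 is smooth everywhere, which
keeps the predicted charges — and hence the potential-energy surface —
continuously differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["swish", "swish_derivative", "DenseNetwork", "Standardizer"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def swish(x, beta: float = 3.0):
    """A(x) = x / (1 + exp(−βx)) = x·σ(βx)."""
    x = np.asarray(x, dtype=float)
    out = x * _sigmoid(beta * x)
    return out if out.ndim else float(out)


def swish_derivative(x, beta: float = 3.0):
    """A'(x) = σ(βx)·(1 + βx·(1 − σ(βx)))."""
    x = np.asarray(x, dtype=float)
    s = _sigmoid(beta * x)
    out = s * (1.0 + beta * x * (1.0 - s))
    return out if out.ndim else float(out)


@dataclass
class Standardizer:
    """Affine feature/label standardization frozen at training time."""

    mean: np.ndarray
    std: np.ndarray

    @classmethod
    def fit(cls, x: np.ndarray, floor: float = 1e-12) -> "Standardizer":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        std = x.std(axis=0)
        return cls(x.mean(axis=0), np.where(std < floor, 1.0, std))

    @classmethod
    def identity(cls, n: int) -> "Standardizer":
        return cls(np.zeros(n), np.ones(n))

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (x - self.mean) / self.std

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.std + self.mean


class DenseNetwork:
    """Scalar-output dense network: input → 4 × hidden (Swish) → linear.

    Parameters
    ----------
    n_input : int
        Feature dimension.
    hidden : tuple of int
        Hidden-layer widths; exactly four layers by construction.
    beta : float
        Swish inverse temperature (default 3).
    rng : numpy Generator or int, optional
        Source for He-style weight initialization.
    """

    N_HIDDEN_LAYERS = 4

    def __init__(self, n_input: int, hidden: tuple[int, ...] = (64, 64, 64, 64),
                 beta: float = 3.0, rng=None, init_scale: float = 1.0):
        if len(hidden) != self.N_HIDDEN_LAYERS:
            raise ValueError("exactly four hidden layers are required")
        if beta <= 0:
            raise ValueError("beta must be positive")
        self.beta = float(beta)
        self.widths = (int(n_input), *map(int, hidden), 1)
        rng = np.random.default_rng(rng)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(self.widths[:-1], self.widths[1:]):
            scale = init_scale * np.sqrt(2.0 / fan_in)
            self.weights.append(rng.normal(0.0, scale, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    # -- inference ---------------------------------------------------------
    @property
    def n_input(self) -> int:
        return self.widths[0]

    def _forward_cached(self, x: np.ndarray):
        """Returns output (B,) and pre-activations for backprop."""
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.n_input:
            raise ValueError(
                f"feature width {x.shape[1]} != network input {self.n_input}")
        acts = [x]
        pre = []
        h = x
        for li in range(self.N_HIDDEN_LAYERS):
            z = h @ self.weights[li] + self.biases[li]
            pre.append(z)
            h = swish(z, self.beta)
            acts.append(h)
        y = h @ self.weights[-1] + self.biases[-1]
        return y[:, 0], acts, pre

    def forward(self, x: np.ndarray) -> np.ndarray:
        """Batched scalar output, shape (B,) (or scalar for a 1-D input)."""
        single = np.asarray(x).ndim == 1
        y, _, _ = self._forward_cached(x)
        return float(y[0]) if single else y

    def input_gradient(self, x: np.ndarray) -> np.ndarray:
        """Exact dY/dX, shape (B, n_input) (or (n_input,) for 1-D input)."""
        single = np.asarray(x).ndim == 1
        _, _, pre = self._forward_cached(x)
        g = np.repeat(self.weights[-1].T, len(pre[0]), axis=0)   # (B, h4)
        for li in range(self.N_HIDDEN_LAYERS - 1, -1, -1):
            g = (g * swish_derivative(pre[li], self.beta)) @ self.weights[li].T
        return g[0] if single else g

    def value_and_input_gradient(self, x: np.ndarray):
        y, _, pre = self._forward_cached(x)
        g = np.repeat(self.weights[-1].T, len(pre[0]), axis=0)
        for li in range(self.N_HIDDEN_LAYERS - 1, -1, -1):
            g = (g * swish_derivative(pre[li], self.beta)) @ self.weights[li].T
        return y, g

    # -- training support --------------------------------------------------
    def parameter_gradients(self, x: np.ndarray, dl_dy: np.ndarray):
        """Backprop dL/dW, dL/db for per-sample output cotangents dl_dy (B,)."""
        y, acts, pre = self._forward_cached(x)
        gw = [np.empty_like(w) for w in self.weights]
        gb = [np.empty_like(b) for b in self.biases]
        delta = np.asarray(dl_dy, dtype=float)[:, None]          # (B, 1)
        gw[-1] = acts[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        for li in range(self.N_HIDDEN_LAYERS - 1, -1, -1):
            delta = (delta @ self.weights[li + 1].T) * swish_derivative(pre[li], self.beta)
            gw[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
        return y, gw, gb

    def mse_gradients(self, x: np.ndarray, y_target: np.ndarray):
        """Single-pass MSE loss + parameter gradients for one minibatch."""
        y, acts, pre = self._forward_cached(x)
        resid = y - np.asarray(y_target, dtype=float)
        loss = float(np.mean(resid ** 2))
        delta = (2.0 * resid / len(resid))[:, None]
        gw = [np.empty_like(w) for w in self.weights]
        gb = [np.empty_like(b) for b in self.biases]
        gw[-1] = acts[-1].T @ delta
        gb[-1] = delta.sum(axis=0)
        for li in range(self.N_HIDDEN_LAYERS - 1, -1, -1):
            delta = (delta @ self.weights[li + 1].T) * swish_derivative(pre[li], self.beta)
            gw[li] = acts[li].T @ delta
            gb[li] = delta.sum(axis=0)
        return loss, gw, gb

    def get_parameters(self) -> list[np.ndarray]:
        return [a.copy() for a in (*self.weights, *self.biases)]

    def set_parameters(self, params: list[np.ndarray]) -> None:
        k = len(self.weights)
        self.weights = [np.asarray(p, dtype=float).copy() for p in params[:k]]
        self.biases = [np.asarray(p, dtype=float).copy() for p in params[k:]]

    # -- serialization -----------------------------------------------------
    def to_arrays(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {f"{prefix}beta": np.asarray(self.beta),
               f"{prefix}widths": np.asarray(self.widths)}
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            out[f"{prefix}w{i}"] = w
            out[f"{prefix}b{i}"] = b
        return out

    @classmethod
    def from_arrays(cls, arrays, prefix: str = "") -> "DenseNetwork":
        widths = [int(v) for v in arrays[f"{prefix}widths"]]
        net = cls(widths[0], tuple(widths[1:-1]), beta=float(arrays[f"{prefix}beta"]))
        net.weights = [np.asarray(arrays[f"{prefix}w{i}"], dtype=float)
                       for i in range(len(widths) - 1)]
        net.biases = [np.asarray(arrays[f"{prefix}b{i}"], dtype=float)
                      for i in range(len(widths) - 1)]
        return net

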