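"""Training of the charge / charge-transfer networks on labelled features.

The loss is the mean squared error on standardized labels; optimization is
minibatch Adam.  "Early stopping with 200 epochs" is implemented as a
200-epoch cap with restoration of the best-validation weights.  Every
stochastic choice (initialization, shuffling) is driven by one explicit
seed, so training runs are bitwise reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .charges import ChargePredictor
from .descriptors import ICFSpec
from .network import DenseNetwork, Standardizer

__all__ = ["TrainingResult", "train_network", "fit_charge_predictor",
           "mean_absolute_error", "r_squared"]


def mean_absolute_error(y_true, y_pred) -> float:
    return float(np.mean(np.abs(np.asarray(y_true) - np.asarray(y_pred))))


def r_squared(y_true, y_pred) -> float:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return 1.0 - ss_res / ss_tot if ss_tot > 0 else float(ss_res == 0.0)


@dataclass
class TrainingResult:
    """Fit record: the trained network, standardizers, and history."""

    network: DenseNetwork
    x_std: Standardizer
    y_std: Standardizer
    train_loss: list = field(default_factory=list)   # standardized MSE
    val_loss: list = field(default_factory=list)
    best_epoch: int = 0
    n_train: int = 0

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.y_std.inverse(self.network.forward(self.x_std.transform(x)))

    def evaluate(self, x: np.ndarray, y: np.ndarray) -> dict:
        pred = self.predict(x)
        return {"mae": mean_absolute_error(y, pred),
                "r2": r_squared(y, pred),
                "rmse": float(np.sqrt(np.mean((pred - np.asarray(y)) ** 2)))}


class _Adam:
    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        lr_t = self.lr * np.sqrt(1.0 - self.b2 ** self.t) / (1.0 - self.b1 ** self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p -= lr_t * m / (np.sqrt(v) + self.eps)


def train_network(x_train: np.ndarray, y_train: np.ndarray,
                  x_val: np.ndarray, y_val: np.ndarray,
                  hidden: tuple[int, ...] = (64, 64, 64, 64),
                  beta: float = 3.0, epochs: int = 200, batch_size: int = 256,
                  learning_rate: float = 1e-3, lr_decay: float = 0.995,
                  seed: int = 0, verbose: bool = False) -> TrainingResult:
    """Fit one scalar-output network; returns the best-validation model."""
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    x_std = Standardizer.fit(x_train)
    y_std = Standardizer.fit(y_train[:, None])
    xt = x_std.transform(x_train)
    yt = y_std.transform(y_train[:, None]).ravel()
    xv = x_std.transform(np.asarray(x_val, dtype=float))
    yv = y_std.transform(np.asarray(y_val, dtype=float).reshape(-1, 1)).ravel()

    net = DenseNetwork(x_train.shape[1], hidden, beta=beta, rng=rng)
    params = [*net.weights, *net.biases]
    opt = _Adam(params, lr=learning_rate)
    result = TrainingResult(net, x_std, y_std, n_train=len(yt))
    best_val = np.inf
    best_params = net.get_parameters()
    n = len(yt)
    for epoch in range(epochs):
        order = rng.permutation(n)
        running = 0.0
        for lo in range(0, n, batch_size):
            idx = order[lo:lo + batch_size]
            xb, yb = xt[idx], yt[idx]
            loss, gw, gb = net.mse_gradients(xb, yb)
            opt.step(params, [*gw, *gb])
            running += loss * len(idx)
        opt.lr *= lr_decay
        train_mse = running / n
        val_pred = net.forward(xv)
        val_mse = float(np.mean((val_pred - yv) ** 2)) if len(yv) else train_mse
        result.train_loss.append(train_mse)
        result.val_loss.append(val_mse)
        if val_mse < best_val:
            best_val = val_mse
            best_params = net.get_parameters()
            result.best_epoch = epoch
        if verbose and epoch % 10 == 0:
            print(f"epoch {epoch:4d}  train {train_mse:.3e}  val {val_mse:.3e}")
    net.set_parameters(best_params)
    return result


def fit_charge_predictor(dataset, spec: ICFSpec | None = None,
                         hidden: tuple[int, ...] = (64, 64, 64, 64),
                         epochs: int = 200, seed: int = 0,
                         train_ct: bool = True,
                         **train_kw) -> tuple[ChargePredictor, dict]:
    """Train the O, H (and optionally CT) networks from a TrainingSet.

    Returns the assembled :class:`ChargePredictor` plus the per-network
    :class:`TrainingResult` records.
    """
    spec = spec or ICFSpec()
    results = {}
    nets = {}
    jobs = [("O", "net_o"), ("H", "net_h")] + ([("CT", "net_ct")] if train_ct else [])
    for off, (el, attr) in enumerate(jobs):
        xtr, ytr = dataset.subset(el, "train")
        xva, yva = dataset.subset(el, "val")
        res = train_network(xtr, ytr, xva, yva, hidden=hidden, epochs=epochs,
                            seed=seed + off, **train_kw)
        results[el] = res
        nets[attr] = res
    if not train_ct:
        ct_net = DenseNetwork(spec.n_ct_features, hidden, rng=seed)
        ct = TrainingResult(ct_net, Standardizer.identity(spec.n_ct_features),
                            Standardizer.identity(1))
        nets["net_ct"] = ct
    predictor = ChargePredictor(
        nets["net_o"].network, nets["net_h"].network, nets["net_ct"].network,
        spec=spec,
        x_std_o=nets["net_o"].x_std, x_std_h=nets["net_h"].x_std,
        x_std_ct=nets["net_ct"].x_std,
        y_std_o=nets["net_o"].y_std, y_std_h=nets["net_h"].y_std,
        y_std_ct=nets["net_ct"].y_std)
    return predictor, results
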