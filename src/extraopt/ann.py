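"""Feed-forward neural-network surrogate trained by momentum backpropagation.

A single-hidden-layer perceptron maps the coded process factors to the
extraction yield.  The reference configuration is a 4-9-1 topology with a
hyperbolic-tangent hidden layer and a linear output, trained by full-batch
gradient descent on the mean squared error with a momentum term:

    dw(t) = -eta * dMSE/dw + mu * dw(t-1)

with learning rate eta = 0.1 and momentum mu = 0.7.  Inputs and the output
are affinely rescaled to [-1, 1] before training.  An optional validation
split provides early stopping: training halts when the validation MSE has
failed to improve for ``patience`` consecutive epochs, and the weights at
the best validation epoch are restored.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import DesignTable

logger = logging.getLogger("extraopt.ann")

_ACTIVATIONS = {
    "tanh": (np.tanh, lambda a: 1.0 - a ** 2),
    "identity": (lambda z: z, lambda a: np.ones_like(a)),
}


class NotFittedError(RuntimeError):
    """The model's scalers have not been fitted (train first)."""


class DivergenceError(RuntimeError):
    """Training loss became non-finite; ``epoch`` records where."""

    def __init__(self, epoch: int):
        self.epoch = epoch
        super().__init__(f"non-finite training loss at epoch {epoch} "
                         "(learning rate too large?)")


@dataclass(frozen=True)
class AnnConfig:
    """Network topology and training hyperparameters.

    Defaults follow the reference study: 4-9-1 topology, learning rate 0.1,
    momentum 0.7, batch (full-gradient) updates, 70/15/15 random data split
    with early-stopping patience of 6 validation failures.
    """

    n_inputs: int = 4
    n_hidden: int = 9
    n_outputs: int = 1
    learning_rate: float = 0.1
    momentum: float = 0.7
    max_epochs: int = 1000
    patience: int = 6
    split: tuple[float, float, float] = (0.70, 0.15, 0.15)
    seed: int = 0
    hidden_activation: str = "tanh"
    output_activation: str = "identity"

    def __post_init__(self) -> None:
        if self.learning_rate <= 0:
            raise ValueError("learning rate must be > 0")
        if not 0 <= self.momentum < 1:
            raise ValueError("momentum must be in [0, 1)")
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError(f"split fractions must sum to 1, got {self.split}")
        if any(s < 0 for s in self.split):
            raise ValueError("split fractions must be non-negative")
        for act in (self.hidden_activation, self.output_activation):
            if act not in _ACTIVATIONS:
                raise ValueError(f"unknown activation {act!r}")
        if min(self.n_inputs, self.n_hidden, self.n_outputs) < 1:
            raise ValueError("all layer sizes must be >= 1")

    def to_dict(self) -> dict:
        return {
            "n_inputs": self.n_inputs, "n_hidden": self.n_hidden,
            "n_outputs": self.n_outputs, "learning_rate": self.learning_rate,
            "momentum": self.momentum, "max_epochs": self.max_epochs,
            "patience": self.patience, "split": list(self.split),
            "seed": self.seed, "hidden_activation": self.hidden_activation,
            "output_activation": self.output_activation,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnnConfig":
        d = dict(d)
        if "split" in d:
            d["split"] = tuple(d["split"])
        return cls(**d)


@dataclass
class MinMaxScaler:
    """Per-column affine map onto [-1, 1]; identity until fitted."""

    lo: np.ndarray | None = None
    hi: np.ndarray | None = None

    @property
    def fitted(self) -> bool:
        return self.lo is not None

    def fit(self, x: np.ndarray) -> "MinMaxScaler":
        x = np.atleast_2d(np.asarray(x, dtype=float))
        self.lo, self.hi = x.min(axis=0), x.max(axis=0)
        # constant columns map to 0 rather than dividing by zero
        self.hi = np.where(self.hi == self.lo, self.lo + 1.0, self.hi)
        return self

    def transform(self, x: np.ndarray) -> np.ndarray:
        if not self.fitted:
            return np.asarray(x, dtype=float)
        return 2.0 * (np.asarray(x, dtype=float) - self.lo) / (self.hi - self.lo) - 1.0

    def inverse(self, s: np.ndarray) -> np.ndarray:
        if not self.fitted:
            return np.asarray(s, dtype=float)
        return (np.asarray(s, dtype=float) + 1.0) / 2.0 * (self.hi - self.lo) + self.lo


@dataclass
class SurrogateModel:
    """Network weights, scalers and training history."""

    config: AnnConfig
    w_hidden: np.ndarray      # (n_inputs, n_hidden)
    b_hidden: np.ndarray      # (n_hidden,)
    w_out: np.ndarray         # (n_hidden, n_outputs)
    b_out: np.ndarray         # (n_outputs,)
    input_scaler: MinMaxScaler = field(default_factory=MinMaxScaler)
    output_scaler: MinMaxScaler = field(default_factory=MinMaxScaler)
    history: pd.DataFrame | None = None

    @property
    def weights(self) -> tuple[np.ndarray, ...]:
        return (self.w_hidden, self.b_hidden, self.w_out, self.b_out)

    def forward_scaled(self, xs: np.ndarray) -> np.ndarray:
        """Forward pass in scaled units."""
        act_h = _ACTIVATIONS[self.config.hidden_activation][0]
        act_o = _ACTIVATIONS[self.config.output_activation][0]
        h = act_h(xs @ self.w_hidden + self.b_hidden)
        return act_o(h @ self.w_out + self.b_out)


def init_network(config: AnnConfig) -> SurrogateModel:
    """Seeded symmetric-uniform initialization scaled by fan-in.

    Each layer's weights and biases are drawn from U(-1/sqrt(fan_in),
    +1/sqrt(fan_in)); scalers start as the identity.
    """
    rng = np.random.default_rng(config.seed)
    r1 = 1.0 / np.sqrt(config.n_inputs)
    r2 = 1.0 / np.sqrt(config.n_hidden)
    return SurrogateModel(
        config=config,
        w_hidden=rng.uniform(-r1, r1, (config.n_inputs, config.n_hidden)),
        b_hidden=rng.uniform(-r1, r1, config.n_hidden),
        w_out=rng.uniform(-r2, r2, (config.n_hidden, config.n_outputs)),
        b_out=rng.uniform(-r2, r2, config.n_outputs),
    )


def _gradients(model: SurrogateModel, xs: np.ndarray, ts: np.ndarray):
    """Analytic MSE gradients for one full batch, in scaled units.

    MSE = mean over samples and outputs of (out - t)^2.
    """
    cfg = model.config
    act_h, dact_h = _ACTIVATIONS[cfg.hidden_activation]
    act_o, dact_o = _ACTIVATIONS[cfg.output_activation]
    h = act_h(xs @ model.w_hidden + model.b_hidden)
    out = act_o(h @ model.w_out + model.b_out)
    n = xs.shape[0] * cfg.n_outputs
    d_out = 2.0 * (out - ts) / n * dact_o(out)
    g_wo = h.T @ d_out
    g_bo = d_out.sum(axis=0)
    d_h = (d_out @ model.w_out.T) * dact_h(h)
    g_wh = xs.T @ d_h
    g_bh = d_h.sum(axis=0)
    mse = float(np.mean((out - ts) ** 2))
    return (g_wh, g_bh, g_wo, g_bo), mse


def _split_indices(n: int, split: tuple[float, float, float],
                   rng: np.random.Generator):
    perm = rng.permutation(n)
    n_tr = int(round(split[0] * n))
    n_va = int(round(split[1] * n))
    n_tr = min(n_tr, n)
    n_va = min(n_va, n - n_tr)
    return perm[:n_tr], perm[n_tr:n_tr + n_va], perm[n_tr + n_va:]


def train(model: SurrogateModel, design: DesignTable,
          config: AnnConfig | None = None) -> SurrogateModel:
    """Train by batch gradient descent with momentum; returns a new model.

    Scalers are fitted on the full dataset before the split (so predictions
    on any run are in-range).  Early stopping applies only when the split
    yields a non-empty validation set.  The per-epoch train/validation/test
    MSE (scaled units) is recorded in ``history``.
    """
    cfg = config or model.config
    mask = design.has_response
    x = design.coded[mask]
    y = design.response[mask].reshape(-1, cfg.n_outputs)

    in_scaler = MinMaxScaler().fit(x)
    out_scaler = MinMaxScaler().fit(y)
    xs = in_scaler.transform(x)
    ts = out_scaler.transform(y)

    rng = np.random.default_rng(cfg.seed)
    tr, va, te = _split_indices(len(xs), cfg.split, rng)
    if len(tr) < 2:
        raise ValueError("training partition needs at least 2 runs")

    weights = [w.copy() for w in model.weights]
    velocity = [np.zeros_like(w) for w in weights]
    work = replace(model, w_hidden=weights[0], b_hidden=weights[1],
                   w_out=weights[2], b_out=weights[3])

    hist = {"epoch": [], "mse_train": [], "mse_val": [], "mse_test": []}
    best_val = np.inf
    best_weights = [w.copy() for w in weights]
    fails = 0
    for epoch in range(1, cfg.max_epochs + 1):
        grads, mse_tr = _gradients(work, xs[tr], ts[tr])
        if not np.isfinite(mse_tr):
            raise DivergenceError(epoch)
        for i in range(4):
            velocity[i] = cfg.momentum * velocity[i] - cfg.learning_rate * grads[i]
            weights[i] += velocity[i]

        mse_va = float(np.mean((work.forward_scaled(xs[va]) - ts[va]) ** 2)) \
            if len(va) else np.nan
        mse_te = float(np.mean((work.forward_scaled(xs[te]) - ts[te]) ** 2)) \
            if len(te) else np.nan
        hist["epoch"].append(epoch)
        hist["mse_train"].append(mse_tr)
        hist["mse_val"].append(mse_va)
        hist["mse_test"].append(mse_te)

        if len(va):
            if mse_va < best_val:
                best_val = mse_va
                best_weights = [w.copy() for w in weights]
                fails = 0
            else:
                fails += 1
                if cfg.patience and fails >= cfg.patience:
                    logger.info("early stop at epoch %d (no validation "
                                "improvement in %d epochs)", epoch, cfg.patience)
                    break

    final = best_weights if len(va) else weights
    return SurrogateModel(
        config=cfg,
        w_hidden=final[0], b_hidden=final[1], w_out=final[2], b_out=final[3],
        input_scaler=in_scaler, output_scaler=out_scaler,
        history=pd.DataFrame(hist),
    )


def fit_surrogate(design: DesignTable, config: AnnConfig) -> SurrogateModel:
    """Initialize and train in one call."""
    return train(init_network(config), design, config)


def predict_ann(model: SurrogateModel, points) -> np.ndarray | float:
    """Deterministic forward pass, descaled to response units."""
    if not (model.input_scaler.fitted and model.output_scaler.fitted):
        raise NotFittedError("model scalers are unfitted; train the model first")
    pts = np.asarray(points, dtype=float)
    scalar = pts.ndim == 1
    out = model.forward_scaled(model.input_scaler.transform(np.atleast_2d(pts)))
    y = model.output_scaler.inverse(out)[:, 0]
    return float(y[0]) if scalar else y


def save_model(model: SurrogateModel, path) -> None:
    """JSON serialization, loadable for bit-exact prediction."""
    d = {
        "config": model.config.to_dict(),
        "w_hidden": model.w_hidden.tolist(),
        "b_hidden": model.b_hidden.tolist(),
        "w_out": model.w_out.tolist(),
        "b_out": model.b_out.tolist(),
        "input_scaler": {"lo": None if model.input_scaler.lo is None
                         else model.input_scaler.lo.tolist(),
                         "hi": None if model.input_scaler.hi is None
                         else model.input_scaler.hi.tolist()},
        "output_scaler": {"lo": None if model.output_scaler.lo is None
                          else model.output_scaler.lo.tolist(),
                          "hi": None if model.output_scaler.hi is None
                          else model.output_scaler.hi.tolist()},
    }
    Path(path).write_text(json.dumps(d, indent=1))


def load_model(path) -> SurrogateModel:
    d = json.loads(Path(path).read_text())

    def scaler(s):
        sc = MinMaxScaler()
        if s["lo"] is not None:
            sc.lo = np.asarray(s["lo"], dtype=float)
            sc.hi = np.asarray(s["hi"], dtype=float)
        return sc

    return SurrogateModel(
        config=AnnConfig.from_dict(d["config"]),
        w_hidden=np.asarray(d["w_hidden"], dtype=float),
        b_hidden=np.asarray(d["b_hidden"], dtype=float),
        w_out=np.asarray(d["w_out"], dtype=float),
        b_out=np.asarray(d["b_out"], dtype=float),
        input_scaler=scaler(d["input_scaler"]),
        output_scaler=scaler(d["output_scaler"]),
    )
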