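"""Feed-forward autoencoder with a fixed-size bottleneck, trained by minibatch Adam.

Implemented directly on numpy so training is fully deterministic given the
config seed.  The decoder mirrors the encoder widths; hidden layers use ReLU
(or linear, by config) while the bottleneck and output layers are linear.  The
optimizer is Adam with a fixed learning rate taken from the hyperparameter
grid (no schedulers).  Grid search trains every (depth, width, learning-rate)
combination and selects the one with minimal test-set reconstruction MSE.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ParameterizationError, ValidationError


@dataclass(frozen=True)
class AEConfig:
    hidden_layers: int = 3
    hidden_units: int = 16
    bottleneck: int = 6
    learning_rate: float = 1e-3
    epochs: int = 200
    batch_size: int = 64
    activation: str = "relu"  # hidden-layer activation: "relu" or "linear"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.bottleneck < 1:
            raise ParameterizationError("bottleneck must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterizationError("learning_rate must be positive")
        if self.hidden_layers < 0 or self.hidden_units < 1:
            raise ParameterizationError("invalid architecture")
        if self.activation not in ("relu", "linear"):
            raise ParameterizationError(f"unknown activation {self.activation!r}")

    def layer_dims(self, input_width: int) -> list[int]:
        enc = [self.hidden_units] * self.hidden_layers
        return [input_width] + enc + [self.bottleneck] + enc[::-1] + [input_width]

    def n_parameters(self, input_width: int) -> int:
        dims = self.layer_dims(input_width)
        return sum(dims[i] * dims[i + 1] + dims[i + 1] for i in range(len(dims) - 1))


@dataclass
class TrainedAE:
    config: AEConfig
    weights: list[np.ndarray] = field(repr=False)
    biases: list[np.ndarray] = field(repr=False)
    train_loss: list[float] = field(default_factory=list)
    test_loss: list[float] = field(default_factory=list)
    diverged: bool = False

    @property
    def input_width(self) -> int:
        return self.weights[0].shape[0]

    @property
    def bottleneck_layer(self) -> int:
        return self.config.hidden_layers + 1  # 1-based layer index of the bottleneck


def _forward(ae_weights, ae_biases, X, activation: str, upto: int | None = None) -> np.ndarray:
    """Run the network; linear on the bottleneck and final layers, else ``activation``."""
    n_layers = len(ae_weights)
    bottleneck_idx = (n_layers // 2) - 1  # 0-based index of the layer producing codes
    h = X
    stop = n_layers if upto is None else upto
    for i in range(stop):
        h = h @ ae_weights[i] + ae_biases[i]
        if i != bottleneck_idx and i != n_layers - 1 and activation == "relu":
            h = np.maximum(h, 0.0)
    return h


def _mse(A: np.ndarray, B: np.ndarray) -> float:
    return float(np.mean((A - B) ** 2))


def fit_autoencoder(X_train, X_test, config: AEConfig) -> TrainedAE:
    """Train by minibatch Adam (fixed learning rate) on reconstruction MSE.

    Deterministic given the config seed.  A non-finite loss marks the result
    as diverged (flagged, not raised) so a grid search can continue past
    pathological learning rates.
    """
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    if X_train.ndim != 2 or X_test.ndim != 2 or X_train.shape[1] != X_test.shape[1]:
        raise ValidationError("train/test must be 2-D with equal widths")
    p = X_train.shape[1]
    if config.bottleneck > p:
        raise ParameterizationError("bottleneck wider than input")

    dims = config.layer_dims(p)
    rng = np.random.default_rng(config.seed)
    weights = [rng.normal(0.0, np.sqrt(2.0 / dims[i]), size=(dims[i], dims[i + 1]))
               for i in range(len(dims) - 1)]
    biases = [np.zeros(dims[i + 1]) for i in range(len(dims) - 1)]
    n_layers = len(weights)
    bottleneck_idx = (n_layers // 2) - 1
    relu = config.activation == "relu"

    # Adam state (beta1=0.9, beta2=0.999, eps=1e-8), one slot per parameter array
    params = weights + biases
    m1 = [np.zeros_like(q) for q in params]
    m2 = [np.zeros_like(q) for q in params]
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    step = 0

    def adam_update(slot: int, grad_arr: np.ndarray) -> None:
        m1[slot] = beta1 * m1[slot] + (1 - beta1) * grad_arr
        m2[slot] = beta2 * m2[slot] + (1 - beta2) * grad_arr**2
        mhat = m1[slot] / (1 - beta1**step)
        vhat = m2[slot] / (1 - beta2**step)
        params[slot] -= config.learning_rate * mhat / (np.sqrt(vhat) + eps)

    ae = TrainedAE(config, weights, biases)
    m = X_train.shape[0]
    with np.errstate(over="ignore", invalid="ignore"):
        for _ in range(config.epochs):
            order = rng.permutation(m)
            for start in range(0, m, config.batch_size):
                batch = X_train[order[start:start + config.batch_size]]
                # forward, caching post-activation values and ReLU masks
                acts = [batch]
                masks: list[np.ndarray | None] = []
                h = batch
                for i in range(n_layers):
                    z = h @ weights[i] + biases[i]
                    if i != bottleneck_idx and i != n_layers - 1 and relu:
                        mask = z > 0
                        h = z * mask
                        masks.append(mask)
                    else:
                        h = z
                        masks.append(None)
                    acts.append(h)
                step += 1
                grad = 2.0 * (acts[-1] - batch) / acts[-1].size
                for i in range(n_layers - 1, -1, -1):
                    if masks[i] is not None:
                        grad = grad * masks[i]
                    gw = acts[i].T @ grad
                    gb = grad.sum(axis=0)
                    grad = grad @ weights[i].T
                    adam_update(i, gw)
                    adam_update(n_layers + i, gb)
            train_mse = _mse(_forward(weights, biases, X_train, config.activation), X_train)
            test_mse = _mse(_forward(weights, biases, X_test, config.activation), X_test)
            ae.train_loss.append(train_mse)
            ae.test_loss.append(test_mse)
            if not (np.isfinite(train_mse) and np.isfinite(test_mse)):
                ae.diverged = True
                break
    return ae


def encode(ae: TrainedAE, X) -> np.ndarray:
    """Bottleneck coordinates for ``X`` (row order preserved)."""
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ae.input_width:
        raise ValidationError(f"expected width {ae.input_width}, got {X.shape}")
    return _forward(ae.weights, ae.biases, X, ae.config.activation,
                    upto=ae.bottleneck_layer)


def reconstruct(ae: TrainedAE, X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != ae.input_width:
        raise ValidationError(f"expected width {ae.input_width}, got {X.shape}")
    return _forward(ae.weights, ae.biases, X, ae.config.activation)


DEFAULT_GRID = {
    "hidden_layers": (2, 3, 4, 5),
    "hidden_units": (10, 12, 16),
    "learning_rate": (0.1, 0.01, 0.001, 0.0001),
}


def grid_search(X_train, X_test, grid: dict | None = None,
                base_config: AEConfig | None = None,
                seed: int = 0) -> tuple[TrainedAE, pd.DataFrame]:
    """Train every grid combination; select minimal test MSE.

    Ties break by fewer parameters, then lower learning rate.  Returns the
    selected model and a results table (one row per combination).
    """
    grid = dict(DEFAULT_GRID if grid is None else grid)
    base = base_config or AEConfig()
    combos = list(itertools.product(grid.get("hidden_layers", (base.hidden_layers,)),
                                    grid.get("hidden_units", (base.hidden_units,)),
                                    grid.get("learning_rate", (base.learning_rate,))))
    if not combos:
        raise ParameterizationError("empty grid")
    p = np.asarray(X_train).shape[1]
    rows = []
    models: list[TrainedAE | None] = []
    for i, (layers, units, lr) in enumerate(combos):
        cfg_seed = int(np.random.SeedSequence((seed, i)).generate_state(1)[0])
        cfg = replace(base, hidden_layers=int(layers), hidden_units=int(units),
                      learning_rate=float(lr), seed=cfg_seed)
        ae = fit_autoencoder(X_train, X_test, cfg)
        models.append(ae)
        rows.append({
            "hidden_layers": int(layers), "hidden_units": int(units),
            "learning_rate": float(lr), "n_parameters": cfg.n_parameters(p),
            "train_mse": ae.train_loss[-1] if ae.train_loss else float("nan"),
            "test_mse": ae.test_loss[-1] if ae.test_loss else float("nan"),
            "diverged": ae.diverged,
        })
    table = pd.DataFrame(rows)
    ok = table.index[~table["diverged"] & np.isfinite(table["test_mse"])]
    if len(ok) == 0:
        raise ValidationError("all grid combinations diverged")
    order = sorted(ok, key=lambda i: (table.at[i, "test_mse"],
                                      table.at[i, "n_parameters"],
                                      table.at[i, "learning_rate"]))
    best = order[0]
    table["selected"] = False
    table.at[best, "selected"] = True
    return models[best], table
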