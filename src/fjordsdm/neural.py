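"""Feedforward neural presence/absence model.

A fully connected network with six covariate inputs, three hidden ReLU
layers of 16, 32 and 64 units, and a single sigmoid output giving the
probability of presence.  Training is plain full-batch gradient descent
with backpropagation on the mean binary cross-entropy plus an L1 penalty
on the weights (biases unpenalized), stopping when the cost has not
improved for `patience` consecutive iterations or at `max_iterations`.
The parameters with the lowest recorded cost are returned.

The monthly update protocol warm-starts each month's training from the
previous month's fitted parameters, so the final model of a multi-year
run is one continuously updated lineage.  Input standardisation (per-
covariate mean/sd) is estimated on the first training month and then
frozen, so warm-started models always see the same input scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .covariates import COVARIATES, EnvStack
from .grids import RasterGrid
from .maxent import TrainingTable

DEFAULT_LAYER_SIZES = (6, 16, 32, 64, 1)


@dataclass
class TrainConfig:
    l1_strength: float = 1e-4
    learning_rate: float = 0.05
    max_iterations: int = 500
    patience: int = 5
    seed: int = 0
    cumulative: bool = False  # retrain on all months seen so far instead of the newest only

    def __post_init__(self) -> None:
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        # max_iterations = 0 is an explicit no-op (warm start passthrough)
        if self.max_iterations != 0 and self.max_iterations < self.patience:
            raise ValueError("max_iterations must be >= patience (or 0 for a no-op)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.l1_strength < 0:
            raise ValueError("l1_strength must be nonnegative")


@dataclass
class MLPModel:
    weights: list  # per layer, (fan_in, fan_out)
    biases: list  # per layer, (fan_out,)
    layer_sizes: tuple = DEFAULT_LAYER_SIZES
    standardization: tuple | None = None  # (mean (6,), sd (6,)) frozen at first fit
    history: list = field(default_factory=list)  # cost per iteration, last training call
    provenance: list = field(default_factory=list)  # month_ids trained on, in order
    seed_chain: list = field(default_factory=list)

    def copy(self) -> "MLPModel":
        return MLPModel(
            [w.copy() for w in self.weights],
            [b.copy() for b in self.biases],
            tuple(self.layer_sizes),
            None if self.standardization is None else tuple(np.array(a) for a in self.standardization),
            list(self.history),
            list(self.provenance),
            list(self.seed_chain),
        )

    def weight_l1(self) -> float:
        return float(sum(np.abs(w).sum() for w in self.weights))


def init_mlp(seed: int, layer_sizes: tuple = DEFAULT_LAYER_SIZES) -> MLPModel:
    """He-initialised network: W ~ N(0, 2/fan_in), biases zero."""
    rng = np.random.default_rng(seed)
    weights, biases = [], []
    for fan_in, fan_out in zip(layer_sizes[:-1], layer_sizes[1:]):
        weights.append(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=(fan_in, fan_out)))
        biases.append(np.zeros(fan_out))
    return MLPModel(weights, biases, tuple(layer_sizes), seed_chain=[seed])


def _forward_full(model: MLPModel, X: np.ndarray):
    """All layer activations; hidden ReLU, sigmoid output."""
    acts = [X]
    a = X
    n_layers = len(model.weights)
    for i, (W, b) in enumerate(zip(model.weights, model.biases)):
        z = a @ W + b
        a = np.where(z > 0, z, 0.0) if i < n_layers - 1 else expit(z)
        acts.append(a)
    return acts


def forward(model: MLPModel, row: np.ndarray) -> float:
    """Predicted presence probability for one standardized covariate row."""
    row = np.asarray(row, dtype=float).reshape(1, -1)
    if not np.all(np.isfinite(row)):
        raise ValueError("non-finite input to forward pass")
    return float(_forward_full(model, row)[-1][0, 0])


def bce_l1_cost(
    predictions: np.ndarray, labels: np.ndarray, model: MLPModel, l1_strength: float
) -> float:
    """Mean cross-entropy −[y log ŷ + (1−y) log(1−ŷ)] plus L1 weight penalty."""
    eps = 1e-12
    p = np.clip(np.asarray(predictions, dtype=float), eps, 1.0 - eps)
    y = np.asarray(labels, dtype=float)
    bce = -np.mean(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    return float(bce + l1_strength * model.weight_l1())


def _gradients(model: MLPModel, X: np.ndarray, y: np.ndarray, l1_strength: float):
    """Backpropagated gradients of the mean BCE + L1 cost."""
    n = len(X)
    acts = _forward_full(model, X)
    yhat = acts[-1].ravel()
    # d cost / d z_out for sigmoid + BCE is (yhat - y) / n
    delta = ((yhat - y) / n).reshape(-1, 1)
    gW = [None] * len(model.weights)
    gb = [None] * len(model.biases)
    for i in range(len(model.weights) - 1, -1, -1):
        gW[i] = acts[i].T @ delta + l1_strength * np.sign(model.weights[i])
        gb[i] = delta.sum(axis=0)
        if i > 0:
            delta = (delta @ model.weights[i].T) * (acts[i] > 0)
    return gW, gb


def _standardize(X: np.ndarray, standardization) -> np.ndarray:
    mean, sd = standardization
    return (X - mean) / sd


def fit_standardization(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    return mean, sd


def train_mlp(
    table: TrainingTable,
    config: TrainConfig,
    warm_start: MLPModel | None = None,
) -> MLPModel:
    """Full-batch gradient descent with early stopping.

    Returns the lowest-cost parameters seen; the cost history (including
    the initial cost) is recorded on the returned model.  Strict-decrease
    comparison with tolerance 1e-12 drives the patience counter.
    """
    if table.m < 1 or table.n < 1:
        raise ValueError("need at least one presence and one background row")
    X_raw = table.X
    y = table.y.astype(float)

    if warm_start is not None:
        model = warm_start.copy()
        if model.standardization is None:
            model.standardization = fit_standardization(X_raw)
    else:
        model = init_mlp(config.seed, (X_raw.shape[1],) + DEFAULT_LAYER_SIZES[1:])
        model.standardization = fit_standardization(X_raw)
    X = _standardize(X_raw, model.standardization)

    def cost_of(mod: MLPModel) -> float:
        yhat = _forward_full(mod, X)[-1].ravel()
        return bce_l1_cost(yhat, y, mod, config.l1_strength)

    best = model.copy()
    best_cost = cost_of(model)
    history = [best_cost]
    stall = 0
    for _ in range(config.max_iterations):
        gW, gb = _gradients(model, X, y, config.l1_strength)
        for i in range(len(model.weights)):
            model.weights[i] -= config.learning_rate * gW[i]
            model.biases[i] -= config.learning_rate * gb[i]
        c = cost_of(model)
        if not np.isfinite(c) or not all(np.all(np.isfinite(w)) for w in model.weights):
            raise FloatingPointError(
                "training diverged to non-finite values; try a smaller learning_rate"
            )
        history.append(c)
        if c < best_cost - 1e-12:
            best_cost = c
            best = model.copy()
            stall = 0
        else:
            stall += 1
            if stall >= config.patience:
                break
    best.history = history
    best.provenance = list(model.provenance)
    best.seed_chain = list(model.seed_chain)
    return best


def update_monthly(
    previous: MLPModel | None,
    month_table: TrainingTable,
    config: TrainConfig,
) -> MLPModel:
    """Warm-started monthly update; provenance appends the month_id."""
    month_id = ""
    if "month_id" in month_table.frame.columns and len(month_table.frame):
        month_id = str(month_table.frame["month_id"].iloc[0])
    if len(month_table.frame) == 0:
        if previous is None:
            raise ValueError("no data and no previous model")
        return previous
    model = train_mlp(month_table, config, warm_start=previous)
    model.provenance = (previous.provenance if previous else []) + [month_id]
    model.seed_chain = (previous.seed_chain if previous else []) + [config.seed]
    return model


def predict_rows(model: MLPModel, X_raw: np.ndarray) -> np.ndarray:
    if model.standardization is None:
        raise RuntimeError("model has no stored input standardization; train it first")
    X = _standardize(np.asarray(X_raw, dtype=float), model.standardization)
    return _forward_full(model, X)[-1].ravel()


def predict_mlp(model: MLPModel, stack: EnvStack) -> RasterGrid:
    """Per-cell forward pass over a stack; nodata propagates."""
    grid = stack.grid
    nodata = stack.combined_nodata()
    arr = stack.as_array().reshape(-1, len(COVARIATES))
    vals = predict_rows(model, arr).reshape(grid.shape)
    vals = np.where(nodata, 0.0, vals)
    return RasterGrid(vals, grid.cell_size, tuple(grid.origin), nodata.copy())


# -- serialization ----------------------------------------------------------

def save_mlp(model: MLPModel, path) -> None:
    """Write the model to a JSON file; round-trip is bit-exact."""
    payload = {
        "layer_sizes": list(model.layer_sizes),
        "weights": [w.tolist() for w in model.weights],
        "biases": [b.tolist() for b in model.biases],
        "standardization": None
        if model.standardization is None
        else [np.asarray(a).tolist() for a in model.standardization],
        "provenance": model.provenance,
        "seed_chain": model.seed_chain,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)


def load_mlp(path) -> MLPModel:
    with open(path) as fh:
        payload = json.load(fh)
    std = payload["standardization"]
    return MLPModel(
        [np.asarray(w) for w in payload["weights"]],
        [np.asarray(b) for b in payload["biases"]],
        tuple(payload["layer_sizes"]),
        None if std is None else (np.asarray(std[0]), np.asarray(std[1])),
        provenance=payload["provenance"],
        seed_chain=payload["seed_chain"],
    )
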