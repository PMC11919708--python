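"""Penalized maximum-entropy presence/background model, from scratch.

The model estimates a Gibbs distribution over the background (pseudo-
absence) points: ``p(x) = exp(eta . f(x)) / Z`` where ``f`` are hinge
features of the six covariates and ``Z`` normalises over the background.
Weights are found by maximising the L1-penalized log-likelihood ("gain")

    G(eta) = (1/m) sum_presence eta.f(x_i)
             - log sum_background Q(x_i) exp(eta.f(x_i))
             - beta * sum_j lambda_j |eta_j|

with uniform background prior Q = 1/n, m presences and n background
points.  G is concave; we maximise it by proximal gradient ascent with
backtracking, starting from eta = 0, so the gain sequence never
decreases.  At eta = 0 the model is the uniform distribution and G = 0.

Only hinge features are generated: for each covariate and each knot k,
a forward hinge max(0, x - k) and a reverse hinge max(0, k - x), each
rescaled to [0, 1] over the training range.  Hinge features alone give
piecewise-linear response curves, which is the configuration used
throughout this analysis.

Prediction maps the normalised Gibbs density to a 0-1 habitat
suitability index via the complementary log-log transform
``1 - exp(-exp(H) * p(x))`` where H is the entropy of the fitted
background distribution (the modern default presentation); a config
switch returns the raw density instead.  Both are monotone in the linear
predictor, so rankings and AUC do not depend on the choice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .covariates import COVARIATES, EnvStack
from .grids import RasterGrid

logger = logging.getLogger(__name__)


@dataclass
class TrainingTable:
    """Covariate rows with binary labels (1 = presence, 0 = background)."""

    frame: pd.DataFrame  # columns: COVARIATES..., label, optionally month_id

    def __post_init__(self) -> None:
        missing = [c for c in COVARIATES if c not in self.frame.columns]
        if missing:
            raise ValueError(f"training table missing covariates: {missing}")
        if "label" not in self.frame.columns:
            raise ValueError("training table missing 'label' column")
        X = self.frame[list(COVARIATES)].to_numpy(dtype=float)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite covariate values in training table")

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(COVARIATES)].to_numpy(dtype=float)

    @property
    def y(self) -> np.ndarray:
        return self.frame["label"].to_numpy(dtype=int)

    @property
    def m(self) -> int:
        return int((self.y == 1).sum())

    @property
    def n(self) -> int:
        return int((self.y == 0).sum())


def make_training_table(presence_rows: pd.DataFrame, absence_rows: pd.DataFrame) -> TrainingTable:
    """Stack extracted presence and pseudo-absence covariate rows."""
    p = presence_rows.copy()
    p["label"] = 1
    a = absence_rows.copy()
    a["label"] = 0
    return TrainingTable(pd.concat([p, a], ignore_index=True))


@dataclass
class HingeBasis:
    """Hinge feature expansion shared by training and prediction.

    Each feature is (covariate index, knot, direction, scale): forward
    features are ``max(0, x - knot) / (hi - knot)``, reverse features
    ``max(0, knot - x) / (knot - lo)``, with (lo, hi) the covariate's
    training range — so every feature lies in [0, 1] on training data.
    """

    cov_index: np.ndarray  # (p,) int
    knots: np.ndarray  # (p,)
    forward: np.ndarray  # (p,) bool
    scale: np.ndarray  # (p,) positive
    train_lo: np.ndarray  # (6,) per-covariate training minimum
    train_hi: np.ndarray  # (6,)

    @property
    def n_features(self) -> int:
        return len(self.knots)

    def transform(self, X: np.ndarray, clamp: bool = False) -> np.ndarray:
        """Feature matrix for raw covariate rows (n, 6) -> (n, p)."""
        X = np.asarray(X, dtype=float)
        if clamp:
            X = np.clip(X, self.train_lo, self.train_hi)
        cols = X[:, self.cov_index]
        raw = np.where(self.forward, cols - self.knots, self.knots - cols)
        return np.maximum(0.0, raw) / self.scale


def build_hinge_basis(table: TrainingTable, knots_per_covariate: int = 30) -> HingeBasis:
    """Knots at empirical quantiles, strictly inside each training range.

    A constant covariate contributes no features (logged, not an error).
    """
    if knots_per_covariate < 1:
        raise ValueError("knots_per_covariate must be >= 1")
    X = table.X
    lo = X.min(axis=0)
    hi = X.max(axis=0)
    cov_idx, knots, forward, scale = [], [], [], []
    qs = (np.arange(knots_per_covariate) + 1) / (knots_per_covariate + 1)
    for j in range(X.shape[1]):
        if hi[j] <= lo[j]:
            logger.info("covariate %s constant in training data: no hinge features", COVARIATES[j])
            continue
        kj = np.unique(np.quantile(X[:, j], qs))
        kj = kj[(kj > lo[j]) & (kj < hi[j])]
        for k in kj:
            cov_idx.extend([j, j])
            knots.extend([k, k])
            forward.extend([True, False])
            scale.extend([hi[j] - k, k - lo[j]])
    return HingeBasis(
        np.asarray(cov_idx, dtype=int),
        np.asarray(knots, dtype=float),
        np.asarray(forward, dtype=bool),
        np.asarray(scale, dtype=float),
        lo,
        hi,
    )


@dataclass
class MaxEntModel:
    """Fitted weights plus everything needed to reproduce predictions."""

    eta: np.ndarray
    basis: HingeBasis
    beta: float
    lambdas: np.ndarray
    log_z: float  # log sum_background exp(eta.f)  (density normaliser)
    entropy: float  # entropy of the fitted background distribution
    n_background: int
    converged: bool = True
    final_gain: float = 0.0
    gain_history: list = field(default_factory=list)

    def linear_predictor(self, X: np.ndarray, clamp: bool = True) -> np.ndarray:
        F = self.basis.transform(X, clamp=clamp)
        return F @ self.eta

    def predict_rows(self, X: np.ndarray, output: str = "cloglog") -> np.ndarray:
        """Suitability for raw covariate rows; see module docstring."""
        s = self.linear_predictor(X)
        # Gibbs density relative to the background normaliser: exp(s) / Z
        p = np.exp(s - self.log_z)
        if output == "raw":
            return p
        if output == "cloglog":
            return 1.0 - np.exp(-np.exp(self.entropy) * p)
        raise ValueError(f"unknown output format {output!r}")


def _penalty_scales(F_all: np.ndarray, m: int) -> np.ndarray:
    """Per-feature L1 scale: sqrt(feature variance / m), MaxEnt-style."""
    var = F_all.var(axis=0)
    return np.sqrt(np.maximum(var, 1e-12) / max(m, 1))


def gain(
    eta: np.ndarray,
    F_presence: np.ndarray,
    F_background: np.ndarray,
    beta: float,
    lambdas: np.ndarray,
) -> float:
    """Evaluate the penalized log-likelihood (gain) at ``eta``."""
    if not (np.all(np.isfinite(F_presence)) and np.all(np.isfinite(F_background))):
        raise ValueError("non-finite feature values")
    m = len(F_presence)
    n = len(F_background)
    s_p = F_presence @ eta
    s_b = F_background @ eta
    # log sum (1/n) exp(s_b), computed stably
    smax = s_b.max() if n else 0.0
    log_term = smax + np.log(np.exp(s_b - smax).sum() / n)
    return float(s_p.sum() / m - log_term - beta * float(lambdas @ np.abs(eta)))


def fit_maxent(
    table: TrainingTable,
    basis: HingeBasis | None = None,
    beta: float = 1.0,
    max_iterations: int = 500,
    tolerance: float = 1e-5,
    knots_per_covariate: int = 30,
) -> MaxEntModel:
    """Maximise the gain by proximal gradient ascent from eta = 0.

    Each iteration takes a gradient step on the smooth part of the gain
    and applies soft-thresholding for the L1 penalty; backtracking halves
    the step until the gain does not decrease, so the recorded gain
    sequence is non-decreasing.  Stops when the gain improves by less
    than ``tolerance`` or after ``max_iterations`` (returned with a
    convergence flag, never an exception).
    """
    if table.m < 1 or table.n < 1:
        raise ValueError("need at least one presence and one background row")
    if basis is None:
        basis = build_hinge_basis(table, knots_per_covariate)
    X, y = table.X, table.y
    F_all = basis.transform(X)
    F_p = F_all[y == 1]
    F_b = F_all[y == 0]
    m, n = len(F_p), len(F_b)
    lambdas = _penalty_scales(F_all, m)

    eta = np.zeros(basis.n_features)
    fbar_p = F_p.mean(axis=0) if m else np.zeros(basis.n_features)
    step = 1.0
    history = [gain(eta, F_p, F_b, beta, lambdas)]
    converged = False
    for _ in range(max_iterations):
        s_b = F_b @ eta
        w = np.exp(s_b - s_b.max())
        w /= w.sum()
        grad = fbar_p - w @ F_b  # gradient of the smooth part
        # Backtracking proximal step
        improved = False
        trial_step = step
        for _bt in range(40):
            cand = eta + trial_step * grad
            thr = trial_step * beta * lambdas
            cand = np.sign(cand) * np.maximum(np.abs(cand) - thr, 0.0)
            g = gain(cand, F_p, F_b, beta, lambdas)
            if g >= history[-1] - 1e-15:
                improved = True
                break
            trial_step *= 0.5
        if not improved:
            converged = True
            break
        eta = cand
        history.append(max(g, history[-1]))
        step = min(trial_step * 1.5, 10.0)
        if history[-1] - history[-2] < tolerance:
            converged = True
            break
    if not converged:
        logger.warning("maxent fit hit max_iterations=%d without converging", max_iterations)

    s_b = F_b @ eta
    log_z = float(s_b.max() + np.log(np.exp(s_b - s_b.max()).sum()))
    p_b = np.exp(s_b - log_z)
    entropy = float(-(p_b * np.log(np.maximum(p_b, 1e-300))).sum())
    return MaxEntModel(
        eta=eta,
        basis=basis,
        beta=beta,
        lambdas=lambdas,
        log_z=log_z,
        entropy=entropy,
        n_background=n,
        converged=converged,
        final_gain=history[-1],
        gain_history=history,
    )


def predict_maxent(model: MaxEntModel, stack: EnvStack, output: str = "cloglog") -> RasterGrid:
    """Suitability map over a covariate stack; nodata propagates.

    Covariate values outside the training range are clamped to it before
    the hinge expansion (standard "clamping" behaviour), logged once.
    """
    grid = stack.grid
    nodata = stack.combined_nodata()
    arr = stack.as_array().reshape(-1, len(COVARIATES))
    out_of_range = np.any((arr < model.basis.train_lo) | (arr > model.basis.train_hi), axis=1)
    if out_of_range.any():
        logger.info("clamped %d cells outside the training covariate range", int(out_of_range.sum()))
    vals = model.predict_rows(arr, output=output).reshape(grid.shape)
    vals = np.where(nodata, 0.0, vals)
    return RasterGrid(vals, grid.cell_size, tuple(grid.origin), nodata.copy())
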