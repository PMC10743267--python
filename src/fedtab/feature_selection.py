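"""L1-regularised logistic feature selection.

The objective is the mean negative log-likelihood of a sigmoid model plus an
L1 penalty on the feature weights (the intercept is never penalised):

    J(theta, b) = -(1/m) * sum_i [ y_i log h_i + (1 - y_i) log(1 - h_i) ]
                  + lambda * ||theta||_1,      h_i = sigmoid(theta.x_i + b)

Minimised by proximal gradient descent (ISTA): a gradient step on the smooth
log-likelihood term followed by soft-thresholding of the feature weights, with
backtracking line search so the objective provably never increases.  The
solver stops when the proximal-gradient residual (the step-normalised change
of the iterate, which at lambda = 0 reduces to the plain gradient) has
sup-norm below ``tol``.  Features whose weights survive at a magnitude above
``zero_tol`` are the selected set.

Raw cytology feature scales span four orders of magnitude, so standardisation
(train-statistics z-scoring) is on by default and weights are reported on the
standardised scale.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_model import ConfigError, FedtabError, FeatureTable, SplitSpec, split

#: default lambda grid for validation-loss tuning (log-spaced)
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(np.logspace(-4, -0.5, 15))


@dataclass(frozen=True)
class L1Config:
    lambda_: float | str = "grid"  # fixed strength, or "grid" for tuned
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    standardize: bool = True
    tol: float = 1e-6
    max_iter: int = 5000
    zero_tol: float = 1e-8

    def __post_init__(self) -> None:
        if self.tol <= 0:
            raise ConfigError("tol must be > 0")
        if self.max_iter < 1:
            raise ConfigError("max_iter must be >= 1")
        if isinstance(self.lambda_, str):
            if self.lambda_ != "grid":
                raise ConfigError("lambda_ must be a number or 'grid'")
        elif self.lambda_ < 0:
            raise ConfigError("lambda_ must be >= 0")


@dataclass(frozen=True)
class L1FitResult:
    theta: np.ndarray  # per-feature weights (standardised scale if standardize)
    intercept: float
    lambda_: float
    selected: tuple[int, ...]
    n_iter: int
    converged: bool
    objective_value: float
    feature_mean: np.ndarray | None = None  # standardisation parameters
    feature_std: np.ndarray | None = None


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))  # numerically stable


def _nll(theta: np.ndarray, intercept: float, X: np.ndarray, y: np.ndarray) -> float:
    z = X @ theta + intercept
    # log(1 + exp(-|z|)) form avoids overflow
    return float(np.mean(np.logaddexp(0.0, z) - y * z))


def objective(
    theta, intercept: float, X, y, lambda_: float
) -> float:
    """Mean logistic negative log-likelihood plus lambda * ||theta||_1."""
    theta = np.asarray(theta, dtype=float)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[0] != y.shape[0] or X.shape[1] != theta.shape[0]:
        raise FedtabError("dimension mismatch in objective")
    if len(y) and not np.isin(y, (0, 1)).all():
        raise FedtabError("labels must be binary 0/1")
    return _nll(theta, intercept, X, y) + lambda_ * float(np.abs(theta).sum())


def _soft_threshold(v: np.ndarray, t: float) -> np.ndarray:
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0)


def _fit_at_lambda(
    X: np.ndarray, y: np.ndarray, lambda_: float, tol: float, max_iter: int
) -> tuple[np.ndarray, float, int, bool, float]:
    m, d = X.shape
    theta = np.zeros(d)
    intercept = 0.0
    step = 1.0
    obj = objective(theta, intercept, X, y, lambda_)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        p = _sigmoid(X @ theta + intercept)
        resid = p - y
        grad_theta = X.T @ resid / m
        grad_b = float(resid.mean())
        # backtracking: shrink step until the ISTA update decreases J
        while True:
            theta_new = _soft_threshold(theta - step * grad_theta, step * lambda_)
            b_new = intercept - step * grad_b
            obj_new = objective(theta_new, b_new, X, y, lambda_)
            if obj_new <= obj + 1e-15 or step < 1e-12:
                break
            step *= 0.5
        # prox-gradient residual: at lambda = 0 this is the plain gradient
        residual = max(
            float(np.abs(theta_new - theta).max()) / step, abs(b_new - intercept) / step
        )
        theta, intercept, obj = theta_new, b_new, obj_new
        if residual < tol:
            converged = True
            break
        step = min(step * 2.0, 1e4)  # tentative growth keeps steps large
    return theta, intercept, it, converged, obj


def fit_l1_logistic(
    X, y, cfg: L1Config | None = None, seed: int = 0
) -> L1FitResult:
    """Fit the penalised sigmoid model; tunes lambda on a validation split if asked.

    With ``cfg.lambda_ == "grid"`` the data is split 80:20 (seeded), each grid
    value is fit on the training part and scored by validation negative
    log-likelihood, and the winner is chosen by the one-standard-error rule:
    the largest (sparsest) lambda whose validation loss is within one standard
    error of the minimum.  The final model is refit on all rows at that lambda.
    """
    cfg = cfg or L1Config()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if len(X) < 2 or len(np.unique(y)) < 2:
        raise FedtabError("need >= 2 records and both classes present")
    mean = std = None
    if cfg.standardize:
        mean = X.mean(axis=0)
        std = X.std(axis=0)
        std = np.where(std > 0, std, 1.0)
        X = (X - mean) / std
    if cfg.lambda_ == "grid":
        lam = _tune_lambda(X, y, cfg, seed)
    else:
        lam = float(cfg.lambda_)
    theta, intercept, n_iter, converged, obj = _fit_at_lambda(
        X, y, lam, cfg.tol, cfg.max_iter
    )
    fit = L1FitResult(
        theta=theta,
        intercept=intercept,
        lambda_=lam,
        selected=(),
        n_iter=n_iter,
        converged=converged,
        objective_value=obj,
        feature_mean=mean,
        feature_std=std,
    )
    return replace(fit, selected=tuple(select_features(fit, cfg.zero_tol)))


def _tune_lambda(X: np.ndarray, y: np.ndarray, cfg: L1Config, seed: int) -> float:
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(X))
    n_train = int(0.8 * len(X))
    tr, va = order[:n_train], order[n_train:]
    if len(va) == 0 or len(np.unique(y[tr])) < 2:
        return float(cfg.lambda_grid[len(cfg.lambda_grid) // 2])
    losses, ses = [], []
    for lam in cfg.lambda_grid:
        theta, b, *_ = _fit_at_lambda(X[tr], y[tr], lam, cfg.tol, cfg.max_iter)
        z = X[va] @ theta + b
        per_sample = np.logaddexp(0.0, z) - y[va] * z
        losses.append(float(per_sample.mean()))
        ses.append(float(per_sample.std() / np.sqrt(len(va))))
    best = int(np.argmin(losses))
    threshold = losses[best] + ses[best]
    # one-standard-error rule: sparsest lambda statistically tied with the best
    eligible = [lam for lam, loss in zip(cfg.lambda_grid, losses) if loss <= threshold]
    return float(max(eligible))


def lambda_max(X, y) -> float:
    """Smallest lambda at which the all-zero weight vector is optimal."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    return float(np.max(np.abs(X.T @ (y - y.mean()))) / len(y))


def select_features(fit: L1FitResult, zero_tol: float = 1e-8) -> list[int]:
    """Ascending indices of features whose weight magnitude exceeds zero_tol."""
    return [int(j) for j in np.flatnonzero(np.abs(fit.theta) > zero_tol)]


def reduce_table(table: FeatureTable, indices: Sequence[int]) -> FeatureTable:
    """Project the table onto the given feature columns, in the given order."""
    idx = list(indices)
    if not idx:
        raise FedtabError("refusing to reduce to an empty feature set")
    if any(j < 0 or j >= table.n_features for j in idx):
        raise FedtabError(f"feature index out of range in {idx}")
    return replace(
        table,
        features=table.features[:, idx],
        feature_names=tuple(table.feature_names[j] for j in idx),
    )


def select_and_reduce(
    table: FeatureTable, cfg: L1Config | None = None, seed: int = 0
) -> tuple[FeatureTable, L1FitResult]:
    """Convenience wrapper: fit on the table, project onto the surviving features."""
    fit = fit_l1_logistic(table.features, table.labels, cfg, seed)
    indices = list(fit.selected)
    if not indices:  # fully shrunk fit would leave no predictors
        raise FedtabError("L1 selection eliminated every feature; lower lambda_")
    return reduce_table(table, indices), fit
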