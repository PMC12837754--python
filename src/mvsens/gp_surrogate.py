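"""ARD-kernel Gaussian-process regression with a linear baseline.

The covariance is a unit-amplitude squared-exponential with one length
scale per input dimension (automatic relevance determination):

    k(x_i, x_j) = exp( -1/2 * sum_d (x_{i,d} - x_{j,d})^2 / l_d^2 )

A small fixed jitter sigma^2 is added to the kernel matrix for numerical
stability; it is *not* optimized.  The length scales are chosen to
maximize the log marginal likelihood by quasi-Newton ascent in log
space, multi-started from a cross-validation-selected initial guess.
The mean predictor is

    y* = k(x*, X) (K + sigma^2 I)^{-1} y.

Targets are standardized to zero mean and unit variance on the training
data (the kernel has unit amplitude); inputs are left in their physical
units, the per-dimension length scales absorbing scale.  Accuracy is
reported as the coefficient of determination R^2 and the mean absolute
percentage error (MAPE, as a fraction).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from scipy.optimize import minimize

logger = logging.getLogger(__name__)

__all__ = [
    "TrainedGP",
    "LinearModel",
    "FitReport",
    "ard_kernel",
    "kernel_matrix",
    "log_marginal_likelihood",
    "fit_gp",
    "predict_mean",
    "fit_linear",
    "predict_linear",
    "r_squared",
    "mape",
    "cv_init_lengthscale",
    "default_init_grid",
]

#: Default fixed kernel jitter on standardized targets.
DEFAULT_SIGMA2 = 1e-4

#: |y| below this (in output units) is excluded from the MAPE sum.
MAPE_EPS = 1e-6


class ZeroVarianceError(ValueError):
    """Raised when R^2 is requested for a zero-variance target."""


def ard_kernel(xi: np.ndarray, xj: np.ndarray, lengthscales: np.ndarray) -> float:
    """ARD squared-exponential similarity of two input vectors, in (0, 1]."""
    xi = np.asarray(xi, float)
    xj = np.asarray(xj, float)
    l = np.asarray(lengthscales, float)
    if xi.shape != xj.shape or xi.shape != l.shape:
        raise ValueError("xi, xj and lengthscales must have equal shapes")
    if np.any(l <= 0):
        raise ValueError("lengthscales must be strictly positive")
    return float(np.exp(-0.5 * np.sum(((xi - xj) / l) ** 2)))


def _scaled(X: np.ndarray, l: np.ndarray) -> np.ndarray:
    return np.asarray(X, float) / np.asarray(l, float)[None, :]


def kernel_matrix(X1: np.ndarray, X2: np.ndarray, lengthscales: np.ndarray) -> np.ndarray:
    """ARD kernel Gram matrix between two sample sets."""
    A = _scaled(X1, lengthscales)
    B = _scaled(X2, lengthscales)
    sq = (
        np.sum(A**2, axis=1)[:, None]
        + np.sum(B**2, axis=1)[None, :]
        - 2.0 * (A @ B.T)
    )
    return np.exp(-0.5 * np.clip(sq, 0.0, None))


def _chol(X: np.ndarray, l: np.ndarray, sigma2: float):
    K = kernel_matrix(X, X, l)
    K[np.diag_indices_from(K)] += sigma2
    try:
        return cho_factor(K, lower=True)
    except LinAlgError as exc:  # pragma: no cover - jitter makes this rare
        cond = np.linalg.cond(K)
        raise LinAlgError(
            f"kernel matrix (n={len(X)}, sigma2={sigma2}) is not positive "
            f"definite; condition number {cond:.3e}"
        ) from exc


def log_marginal_likelihood(
    X: np.ndarray, y: np.ndarray, lengthscales: np.ndarray, sigma2: float = DEFAULT_SIGMA2
) -> float:
    """GP evidence of targets ``y`` under the ARD kernel with jitter."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    c = _chol(X, np.asarray(lengthscales, float), sigma2)
    alpha = cho_solve(c, y)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    return float(-0.5 * y @ alpha - 0.5 * logdet - 0.5 * len(y) * np.log(2.0 * np.pi))


def _lml_and_grad(X, y, log_l, sigma2):
    """Evidence and its gradient with respect to log lengthscales."""
    l = np.exp(log_l)
    n = len(y)
    K0 = kernel_matrix(X, X, l)
    K = K0.copy()
    K[np.diag_indices_from(K)] += sigma2
    c = cho_factor(K, lower=True)
    alpha = cho_solve(c, y)
    logdet = 2.0 * np.sum(np.log(np.diag(c[0])))
    lml = -0.5 * y @ alpha - 0.5 * logdet - 0.5 * n * np.log(2.0 * np.pi)
    Kinv = cho_solve(c, np.eye(n))
    W = np.outer(alpha, alpha) - Kinv
    grad = np.empty_like(l)
    for d in range(X.shape[1]):
        diff = (X[:, d][:, None] - X[:, d][None, :]) / l[d]
        dK = K0 * diff**2  # d K0 / d log l_d
        grad[d] = 0.5 * np.sum(W * dK)
    return float(lml), grad


@dataclasses.dataclass
class TrainedGP:
    """A fitted ARD Gaussian process (zero prior mean on standardized y)."""

    lengthscales: np.ndarray
    sigma2: float
    X_train: np.ndarray
    y_train: np.ndarray       # original units
    y_mean: float
    y_std: float
    alpha: np.ndarray         # (K + sigma2 I)^{-1} y_standardized
    log_marginal: float
    constant_target: bool = False

    def to_json(self) -> str:
        return json.dumps(
            {
                "lengthscales": self.lengthscales.tolist(),
                "sigma2": self.sigma2,
                "X_train": self.X_train.tolist(),
                "y_train": self.y_train.tolist(),
                "y_mean": self.y_mean,
                "y_std": self.y_std,
                "log_marginal": self.log_marginal,
                "constant_target": self.constant_target,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TrainedGP":
        d = json.loads(text)
        X = np.asarray(d["X_train"], float)
        y = np.asarray(d["y_train"], float)
        gp = cls(
            lengthscales=np.asarray(d["lengthscales"], float),
            sigma2=float(d["sigma2"]),
            X_train=X,
            y_train=y,
            y_mean=float(d["y_mean"]),
            y_std=float(d["y_std"]),
            alpha=np.empty(0),
            log_marginal=float(d["log_marginal"]),
            constant_target=bool(d["constant_target"]),
        )
        if not gp.constant_target:
            ys = (y - gp.y_mean) / gp.y_std
            gp.alpha = cho_solve(_chol(X, gp.lengthscales, gp.sigma2), ys)
        return gp


def fit_gp(
    X: np.ndarray,
    y: np.ndarray,
    init_lengthscales: np.ndarray,
    sigma2: float = DEFAULT_SIGMA2,
    n_restarts: int = 2,
    seed: int = 0,
    maxiter: int = 120,
) -> TrainedGP:
    """Fit the ARD length scales by evidence maximization.

    The optimizer runs in log space from ``init_lengthscales`` plus
    ``n_restarts`` jittered restarts; the best evidence wins.  ``sigma2``
    stays fixed.  A constant target is handled degenerately (the model
    predicts the constant).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if len(X) != len(y):
        raise ValueError("X and y lengths differ")
    if len(y) < 2:
        raise ValueError("need at least 2 training samples")
    init = np.asarray(init_lengthscales, float)
    if np.any(init <= 0):
        raise ValueError("initial lengthscales must be positive")
    y_mean = float(y.mean())
    y_std = float(y.std())
    if y_std < 1e-12:
        return TrainedGP(init, sigma2, X, y, y_mean, 1.0, np.zeros(len(y)),
                         log_marginal=np.nan, constant_target=True)
    ys = (y - y_mean) / y_std

    rng = np.random.default_rng(seed)
    starts = [np.log(init)]
    for _ in range(n_restarts):
        starts.append(np.log(init) + rng.normal(0.0, 0.3, size=init.shape))

    def objective(log_l):
        lml, grad = _lml_and_grad(X, ys, log_l, sigma2)
        return -lml, -grad

    best = None
    for s in starts:
        try:
            res = minimize(objective, s, jac=True, method="L-BFGS-B",
                           bounds=[(-30.0, 30.0)] * len(init),
                           options={"maxiter": maxiter})
        except LinAlgError:
            continue
        if best is None or res.fun < best.fun:
            best = res
    if best is None:
        raise RuntimeError("evidence optimization failed from every start")
    if not best.success:
        logger.info("lengthscale optimizer stopped early: %s", best.message)
    l_opt = np.exp(best.x)
    alpha = cho_solve(_chol(X, l_opt, sigma2), ys)
    return TrainedGP(
        lengthscales=l_opt,
        sigma2=sigma2,
        X_train=X,
        y_train=y,
        y_mean=y_mean,
        y_std=y_std,
        alpha=alpha,
        log_marginal=float(-best.fun),
    )


def predict_mean(gp: TrainedGP, Xstar: np.ndarray, chunk: int = 20000) -> np.ndarray:
    """GP mean prediction in original target units."""
    Xstar = np.atleast_2d(np.asarray(Xstar, float))
    if Xstar.shape[1] != gp.X_train.shape[1]:
        raise ValueError(
            f"Xstar has {Xstar.shape[1]} columns, expected {gp.X_train.shape[1]}"
        )
    if gp.constant_target:
        return np.full(len(Xstar), gp.y_mean)
    out = np.empty(len(Xstar))
    for start in range(0, len(Xstar), chunk):
        part = Xstar[start : start + chunk]
        k = kernel_matrix(part, gp.X_train, gp.lengthscales)
        out[start : start + len(part)] = k @ gp.alpha
    return out * gp.y_std + gp.y_mean


# ---------------------------------------------------------------------------
# Linear baseline
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class LinearModel:
    intercept: float
    coefficients: np.ndarray


def fit_linear(X: np.ndarray, y: np.ndarray) -> LinearModel:
    """Ordinary least squares with intercept; warns on rank deficiency."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if len(X) <= X.shape[1]:
        raise ValueError("need n > D samples for the linear baseline")
    A = np.column_stack([np.ones(len(X)), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        warnings.warn(
            f"design matrix is rank deficient (rank {rank} < {A.shape[1]})",
            RuntimeWarning,
        )
    return LinearModel(intercept=float(coef[0]), coefficients=coef[1:])


def predict_linear(model: LinearModel, Xstar: np.ndarray) -> np.ndarray:
    Xstar = np.atleast_2d(np.asarray(Xstar, float))
    if Xstar.shape[1] != len(model.coefficients):
        raise ValueError("dimension mismatch")
    return model.intercept + Xstar @ model.coefficients


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def r_squared(y: np.ndarray, yhat: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    A zero-variance target with (numerically) perfect predictions returns
    1.0 by convention; otherwise zero variance is an error.
    """
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be non-empty and equally sized")
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        if ss_res <= 1e-20 * max(1.0, float(np.sum(y**2))):
            return 1.0
        raise ZeroVarianceError("R^2 undefined: target has zero variance")
    return 1.0 - ss_res / ss_tot


def mape(y: np.ndarray, yhat: np.ndarray) -> float:
    """Mean absolute percentage error as a fraction (0.156, not 15.6%).

    Samples with |y| < MAPE_EPS are excluded (the formula divides by y);
    the exclusion count is logged.
    """
    y = np.asarray(y, float).ravel()
    yhat = np.asarray(yhat, float).ravel()
    if y.size == 0 or y.shape != yhat.shape:
        raise ValueError("y and yhat must be non-empty and equally sized")
    keep = np.abs(y) >= MAPE_EPS
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("MAPE: excluded %d near-zero target(s)", n_dropped)
    if not np.any(keep):
        raise ValueError("all targets are below the MAPE zero-exclusion threshold")
    return float(np.mean(np.abs(y[keep] - yhat[keep]) / np.abs(y[keep])))


@dataclasses.dataclass
class FitReport:
    """Test-set accuracy of one model on one train/test split."""

    model: str       # "gp" or "linear"
    split_id: int
    r2: float
    mape: float

    def to_dict(self) -> dict:
        return {"model": self.model, "split_id": self.split_id,
                "r2": self.r2, "mape": self.mape}


# ---------------------------------------------------------------------------
# Cross-validated initial length scale
# ---------------------------------------------------------------------------

def default_init_grid(
    X: np.ndarray, factors: Sequence[float] = (0.1, 0.316, 1.0, 3.16, 10.0)
) -> list[np.ndarray]:
    """Geometric grid of candidate initial length scales.

    Each candidate is a scalar factor times the per-dimension input
    range, covering [0.1, 10] x range.
    """
    X = np.atleast_2d(np.asarray(X, float))
    span = X.max(axis=0) - X.min(axis=0)
    span = np.where(span > 0, span, 1.0)
    return [f * span for f in factors]


def cv_init_lengthscale(
    X: np.ndarray,
    y: np.ndarray,
    candidate_inits: Sequence[np.ndarray],
    k_folds: int = 5,
    seed: int = 0,
    sigma2: float = DEFAULT_SIGMA2,
    maxiter: int = 40,
) -> np.ndarray:
    """Pick the initial length scale by k-fold cross-validation.

    Each candidate seeds an evidence optimization on the training folds;
    the candidate with the highest mean held-out R^2 wins.  Ties are
    broken in favor of the smaller init (by mean log length scale).
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    if len(candidate_inits) == 0:
        raise ValueError("need at least one candidate init")
    if len(y) < k_folds:
        raise ValueError("need at least k_folds samples")
    if len(candidate_inits) == 1:
        return np.asarray(candidate_inits[0], float)
    rng = np.random.default_rng(seed)
    idx = rng.permutation(len(y))
    folds = np.array_split(idx, k_folds)
    scored = []
    for ci, cand in enumerate(candidate_inits):
        cand = np.asarray(cand, float)
        scores = []
        for k in range(k_folds):
            test_idx = folds[k]
            train_idx = np.concatenate([folds[j] for j in range(k_folds) if j != k])
            gp = fit_gp(X[train_idx], y[train_idx], cand, sigma2=sigma2,
                        n_restarts=0, maxiter=maxiter)
            pred = predict_mean(gp, X[test_idx])
            scores.append(r_squared(y[test_idx], pred))
        scored.append((float(np.mean(scores)), -float(np.mean(np.log(cand))), ci))
    scored.sort(reverse=True)
    return np.asarray(candidate_inits[scored[0][2]], float)
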