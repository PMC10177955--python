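"""Regularized neighborhood components analysis (NCA) for a continuous response.

NCA learns one nonnegative weight per feature of a diagonal distance metric

    d_w(i, j) = sum_r w_r^2 * delta_r(x_i, x_j),

where ``delta_r`` is the per-feature absolute (default) or squared
difference.  Each point i picks a stochastic reference neighbor j with
probability

    p_ij = exp(-d_w(i, j) / sigma) / sum_{k != i} exp(-d_w(i, k) / sigma),

and the objective is the expected leave-one-out regression loss plus a ridge
penalty on the weights,

    f(w) = (1/n) sum_i sum_{j != i} p_ij * l(y_i, y_j) + lambda * sum_r w_r^2,

with ``l`` the absolute difference by default.  Features that help predict
the response keep large |w_r|; the penalty drives uninformative weights to
zero, so |w_r| serves as a feature importance.  Minimization uses L-BFGS-B
with the analytic gradient from a deterministic all-ones start.

The O(n^2) pairwise computation is intentional: the method operates on MD
snapshot sets of at most a few thousand points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

__all__ = ["NCAConfig", "NCAModel", "nca_objective", "fit_nca", "cross_validate_lambda"]

logger = logging.getLogger(__name__)

#: default CV grid: logarithmic over [1e-3, 3], covering the useful range of
#: the squared-weight penalty for standardized features
DEFAULT_LAMBDA_GRID = tuple(np.geomspace(1e-3, 3.0, 20))

DEFAULT_LAMBDA = 0.05


@dataclass
class NCAConfig:
    """Tunable knobs of the NCA fit.

    sigma
        Kernel width of the neighbor softmax; 1 is appropriate for
        standardized features.
    distance
        ``l1`` (absolute per-feature difference, default) or ``l2`` (squared).
    loss
        ``absolute`` (default) or ``squared`` response loss.
    report
        How importances are reported from the raw weights: ``abs`` (|w|,
        default; sign is not identifiable) or ``squared`` (w^2, the metric
        coefficients).
    """

    sigma: float = 1.0
    distance: str = "l1"
    loss: str = "absolute"
    report: str = "abs"
    max_iter: int = 200
    gtol: float = 1e-6
    lambda_grid: tuple[float, ...] = DEFAULT_LAMBDA_GRID
    n_folds: int = 4
    n_starts: int = 1  # >1 adds seeded perturbed restarts, best objective kept

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.distance not in ("l1", "l2"):
            raise ValueError("distance must be 'l1' or 'l2'")
        if self.loss not in ("absolute", "squared"):
            raise ValueError("loss must be 'absolute' or 'squared'")
        if self.report not in ("abs", "squared"):
            raise ValueError("report must be 'abs' or 'squared'")
        if self.max_iter < 1 or self.n_folds < 2 or self.n_starts < 1:
            raise ValueError("max_iter >= 1, n_folds >= 2, n_starts >= 1 required")
        grid = tuple(float(g) for g in self.lambda_grid)
        if any(g < 0 for g in grid) or list(grid) != sorted(grid):
            raise ValueError("lambda grid must be nonnegative and ascending")
        self.lambda_grid = grid


@dataclass
class NCAModel:
    """Result of one NCA fit: raw weights plus convergence metadata."""

    weights: np.ndarray
    lam: float
    objective_value: float
    converged: bool
    iterations: int
    config: NCAConfig = field(default_factory=NCAConfig)
    seed: int | None = None
    init: str = "ones"

    @property
    def importances(self) -> np.ndarray:
        """Nonnegative per-feature importances (|w| or w^2 per config)."""
        if self.config.report == "squared":
            return self.weights**2
        return np.abs(self.weights)


def _check_xy(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    if X.ndim != 2:
        raise ValueError("X must be 2-D")
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y row counts differ")
    if X.shape[0] < 2:
        raise ValueError("NCA needs at least 2 samples")
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in X or y")
    return X, y


def _loss_matrix(y: np.ndarray, loss: str) -> np.ndarray:
    diff = y[:, None] - y[None, :]
    return np.abs(diff) if loss == "absolute" else diff**2


def _neighbor_probabilities(d: np.ndarray, sigma: float) -> np.ndarray:
    """Row-stochastic softmax of -d/sigma with zero diagonal (log-sum-exp safe)."""
    logits = -d / sigma
    np.fill_diagonal(logits, -np.inf)
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    np.fill_diagonal(P, 0.0)  # exp(-inf - max) already 0, but be explicit
    P /= P.sum(axis=1, keepdims=True)
    return P


def nca_objective(
    w: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    config: NCAConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Objective value and analytic gradient at weights ``w``.

    The gradient of the data term with respect to ``w_r`` is

        (2 w_r / (n sigma)) * sum_ij p_ij * delta_r(i, j) * (L_i - l_ij),

    with ``L_i = sum_j p_ij l_ij`` the expected loss of point i; the penalty
    contributes ``2 lambda w_r``.
    """
    config = config or NCAConfig()
    X, y = _check_xy(X, y)
    w = np.asarray(w, float)
    n, p = X.shape
    if w.shape != (p,):
        raise ValueError(f"weights must have shape ({p},)")

    w2 = w**2
    # pairwise weighted distance, feature by feature (avoids an n^2 x p tensor)
    d = np.zeros((n, n))
    for r in range(p):
        dr = np.abs(X[:, r, None] - X[None, :, r])
        if config.distance == "l2":
            dr = dr**2
        d += w2[r] * dr
    P = _neighbor_probabilities(d, config.sigma)
    L = _loss_matrix(y, config.loss)
    Li = (P * L).sum(axis=1)
    value = float(Li.mean() + lam * w2.sum())

    M = P * (Li[:, None] - L)
    grad = np.empty(p)
    for r in range(p):
        dr = np.abs(X[:, r, None] - X[None, :, r])
        if config.distance == "l2":
            dr = dr**2
        grad[r] = (2.0 * w[r] / (n * config.sigma)) * float((M * dr).sum())
    grad += 2.0 * lam * w
    return value, grad


def fit_nca(
    X: np.ndarray,
    y: np.ndarray,
    lam: float = DEFAULT_LAMBDA,
    config: NCAConfig | None = None,
    seed: int | None = None,
) -> NCAModel:
    """Minimize the NCA objective with L-BFGS-B from the all-ones start.

    ``seed`` only matters when ``config.n_starts > 1``, where additional
    starts perturb the all-ones init with seeded Gaussian noise and the best
    final objective wins.  Warns (without raising) if the optimizer stops at
    the iteration cap.
    """
    config = config or NCAConfig()
    X, y = _check_xy(X, y)
    p = X.shape[1]
    if lam < 0:
        raise ValueError("lambda must be nonnegative")

    rng = np.random.default_rng(seed)
    starts = [np.ones(p)]
    for _ in range(config.n_starts - 1):
        starts.append(np.ones(p) + 0.1 * rng.standard_normal(p))

    best = None
    for s, w0 in enumerate(starts):
        res = minimize(
            nca_objective,
            w0,
            args=(X, y, lam, config),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": config.max_iter, "gtol": config.gtol},
        )
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.success)
    if not converged:
        warnings.warn(
            f"NCA optimizer did not converge in {config.max_iter} iterations: "
            f"{best.message}",
            stacklevel=2,
        )
    return NCAModel(
        weights=np.asarray(best.x, float),
        lam=float(lam),
        objective_value=float(best.fun),
        converged=converged,
        iterations=int(best.nit),
        config=config,
        seed=seed,
        init="ones" if config.n_starts == 1 else f"ones+{config.n_starts - 1} restarts",
    )


def _kernel_predict(
    w: np.ndarray,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    config: NCAConfig,
) -> np.ndarray:
    """Soft-neighbor regression prediction for held-out points."""
    w2 = np.asarray(w, float) ** 2
    d = np.zeros((X_test.shape[0], X_train.shape[0]))
    for r in range(X_train.shape[1]):
        dr = np.abs(X_test[:, r, None] - X_train[None, :, r])
        if config.distance == "l2":
            dr = dr**2
        d += w2[r] * dr
    logits = -d / config.sigma
    logits -= logits.max(axis=1, keepdims=True)
    P = np.exp(logits)
    P /= P.sum(axis=1, keepdims=True)
    return P @ y_train


def cross_validate_lambda(
    X: np.ndarray,
    y: np.ndarray,
    grid: tuple[float, ...] | None = None,
    k: int | None = None,
    seed: int = 0,
    config: NCAConfig | None = None,
) -> tuple[float, np.ndarray]:
    """Pick the penalty strength by k-fold cross-validation.

    Folds come from a seeded shuffle.  For each candidate lambda the model is
    fitted on k-1 folds and the held-out points are scored with the
    soft-neighbor predictor under mean absolute error.  Returns the grid
    value with the lowest mean CV loss (ties break toward the smaller
    lambda) and the full loss curve.
    """
    config = config or NCAConfig()
    grid = tuple(config.lambda_grid if grid is None else (float(g) for g in grid))
    if not grid:
        raise ValueError("lambda grid is empty")
    k = config.n_folds if k is None else int(k)
    X, y = _check_xy(X, y)
    n = X.shape[0]
    if k < 2 or n < 2 * k:
        raise ValueError(f"need k >= 2 and n >= 2k (got n={n}, k={k})")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)

    losses = np.zeros(len(grid))
    for g, lam in enumerate(grid):
        fold_losses = []
        for f in range(k):
            test = folds[f]
            train = np.concatenate([folds[j] for j in range(k) if j != f])
            model = fit_nca(X[train], y[train], lam, config)
            pred = _kernel_predict(model.weights, X[train], y[train], X[test], config)
            fold_losses.append(float(np.mean(np.abs(pred - y[test]))))
        losses[g] = np.mean(fold_losses)
        logger.debug("lambda=%.4g CV loss=%.6g", lam, losses[g])
    best = int(np.argmin(losses))
    return float(grid[best]), losses
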