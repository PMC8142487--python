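"""Sparse multi-task logistic classification of driver genes.

One task per cancer type.  The model minimizes

    min_W  sum_i L(W_i | X_i, Y_i) + lambda1 ||W||_1 + lambda2 ||W||_F^2

where L is the (per-task mean) logistic loss over that task's genes,
W is the p x t coefficient matrix with one column per task, the L1 term
induces shared sparsity across tasks and the squared-Frobenius term
stabilizes the fit.  The solver is an accelerated proximal-gradient
method (monotone FISTA with backtracking line search): the smooth part
(losses + Frobenius term) is handled by gradient steps, the L1 part by
the closed-form soft-threshold prox.

Conventions, all configurable through :class:`MTLConfig`:

* per-task losses are means over samples so tasks of unequal size
  contribute comparably;
* an intercept by default: a constant-1 column is appended, its row is
  exempt from the L1 penalty but kept in the Frobenius term (driver
  labels are heavily imbalanced, and without an intercept the fit
  contorts feature coefficients into a pseudo-intercept); it can be
  switched off, recovering the objective exactly as written;
* features enter raw; optional z-scoring stores its parameters on the
  model.

Labels are +1 (driver) / -1 (non-driver).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .evaluation import roc_auc
from .io_formats import ContractError

__all__ = [
    "TaskDataset",
    "MTLConfig",
    "MTLModel",
    "sigmoid",
    "soft_threshold",
    "logistic_loss",
    "mtl_objective",
    "lambda1_max",
    "fit_mtl",
    "cv_select_lambda1",
    "select_lambda2_on_validation",
    "predict_probability",
    "select_task_thresholds",
    "classify_drivers",
    "DEFAULT_LAMBDA_GRID",
    "DEFAULT_LAMBDA1",
    "DEFAULT_LAMBDA2",
]

logger = logging.getLogger(__name__)

#: log-spaced default search grid for both penalties, 10^-6 .. 10^2
#: at three points per decade
DEFAULT_LAMBDA_GRID: tuple[float, ...] = tuple(10.0 ** (k / 3) for k in range(-18, 7))
#: shipped defaults used when selection is skipped
DEFAULT_LAMBDA1 = 1e-5
DEFAULT_LAMBDA2 = 1e-4


@dataclass
class TaskDataset:
    """Feature matrix and +/-1 labels for one cancer type."""

    task_name: str
    X: np.ndarray
    Y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        if self.X.ndim != 2:
            raise ContractError("X must be 2-dimensional")
        if len(self.X) != len(self.Y):
            raise ContractError("X and Y lengths differ")
        if np.isnan(self.X).any() or np.isnan(self.Y).any():
            raise ContractError("task data must not contain missing entries")
        if not set(np.unique(self.Y)) <= {-1.0, 1.0}:
            raise ContractError("labels must be in {+1, -1}")

    @property
    def n(self) -> int:
        return len(self.Y)


@dataclass(frozen=True)
class MTLConfig:
    """Solver and model-structure options."""

    add_bias: bool = True
    mean_loss: bool = True
    standardize: bool = False
    max_iter: int = 10_000
    tol: float = 1e-10
    #: sup-norm bound on the proximal-gradient mapping; the objective-change
    #: test alone can trigger on flat directions while coefficients still move
    gtol: float = 1e-7


@dataclass
class MTLModel:
    """Fitted sparse multi-task logistic model.

    ``W`` is (p [+1 bias row]) x t, columns aligned with ``task_names``.
    ``thresholds`` maps task name -> probability cutoff in [0, 1].
    """

    W: np.ndarray
    lambda1: float
    lambda2: float
    task_names: tuple[str, ...]
    feature_order: tuple[str, ...]
    config: MTLConfig = field(default_factory=MTLConfig)
    thresholds: dict[str, float] = field(default_factory=dict)
    converged: bool = True
    n_iter: int = 0
    objective_history: list[float] = field(default_factory=list)
    standardize_mean: np.ndarray | None = None
    standardize_scale: np.ndarray | None = None

    def task_index(self, task_name: str) -> int:
        try:
            return self.task_names.index(task_name)
        except ValueError:
            raise ContractError(
                f"unknown task '{task_name}'; available: {list(self.task_names)}"
            ) from None


def sigmoid(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def soft_threshold(x: np.ndarray, tau: float) -> np.ndarray:
    """Proximal operator of tau * ||.||_1: sign(x) * max(|x| - tau, 0)."""
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def logistic_loss(
    w: np.ndarray, X: np.ndarray, Y: np.ndarray, mean: bool = True
) -> float:
    """Logistic loss mean (or sum) over samples: log(1 + exp(-Y * Xw)).

    Computed through log1p/logaddexp so large margins do not overflow.
    """
    w = np.asarray(w, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float).ravel()
    if X.shape[1] != len(w) or X.shape[0] != len(Y):
        raise ContractError(
            f"dimension mismatch: X {X.shape}, w {len(w)}, Y {len(Y)}"
        )
    margins = Y * (X @ w)
    losses = np.logaddexp(0.0, -margins)  # log(1 + exp(-m)), overflow-safe
    return float(losses.mean() if mean else losses.sum())


def _penalty_mask(p_total: int, add_bias: bool) -> np.ndarray:
    """Boolean mask of rows subject to the L1 penalty (bias row exempt)."""
    mask = np.ones(p_total, dtype=bool)
    if add_bias:
        mask[-1] = False
    return mask


def mtl_objective(
    W: np.ndarray,
    tasks: Sequence[TaskDataset],
    lambda1: float,
    lambda2: float,
    config: MTLConfig | None = None,
) -> float:
    """Full objective: sum of per-task losses + L1 + squared Frobenius.

    With an intercept enabled, the bias row is excluded from the L1 term
    but included in the Frobenius term.
    """
    config = config or MTLConfig()
    if lambda1 < 0 or lambda2 < 0:
        raise ContractError("penalty weights must be non-negative")
    W = np.asarray(W, dtype=float)
    loss = sum(
        logistic_loss(W[:, i], t.X, t.Y, mean=config.mean_loss)
        for i, t in enumerate(tasks)
    )
    mask = _penalty_mask(W.shape[0], config.add_bias)
    l1 = float(np.abs(W[mask]).sum())
    frob2 = float((W ** 2).sum())
    return loss + lambda1 * l1 + lambda2 * frob2


# ---------------------------------------------------------------------------
# solver internals

def _design_matrices(
    tasks: Sequence[TaskDataset], config: MTLConfig
) -> tuple[list[np.ndarray], np.ndarray | None, np.ndarray | None]:
    """Optionally standardize and append the constant-1 bias column."""
    mean = scale = None
    Xs = [t.X for t in tasks]
    if config.standardize:
        stacked = np.vstack(Xs)
        mean = stacked.mean(axis=0)
        scale = stacked.std(axis=0)
        scale[scale == 0] = 1.0
        Xs = [(X - mean) / scale for X in Xs]
    if config.add_bias:
        Xs = [np.hstack([X, np.ones((len(X), 1))]) for X in Xs]
    return Xs, mean, scale


def _smooth_value_grad(
    W: np.ndarray,
    Xs: Sequence[np.ndarray],
    Ys: Sequence[np.ndarray],
    lambda2: float,
    mean_loss: bool,
) -> tuple[float, np.ndarray]:
    """Value and gradient of the smooth part (losses + Frobenius term)."""
    value = 0.0
    grad = 2.0 * lambda2 * W
    for i, (X, Y) in enumerate(zip(Xs, Ys)):
        margins = Y * (X @ W[:, i])
        value += float(np.logaddexp(0.0, -margins).mean()
                       if mean_loss else np.logaddexp(0.0, -margins).sum())
        # d/dw mean log(1+exp(-m)) = -X^T (Y * sigmoid(-m)) / n
        weights = Y * sigmoid(-margins)
        g = -(X.T @ weights)
        if mean_loss:
            g /= len(Y)
        grad[:, i] += g
    value += lambda2 * float((W ** 2).sum())
    return value, grad


def _prox(W: np.ndarray, tau: float, mask: np.ndarray) -> np.ndarray:
    out = W.copy()
    out[mask] = soft_threshold(W[mask], tau)
    return out


def fit_mtl(
    tasks: Sequence[TaskDataset],
    lambda1: float = DEFAULT_LAMBDA1,
    lambda2: float = DEFAULT_LAMBDA2,
    config: MTLConfig | None = None,
    feature_order: Sequence[str] | None = None,
    seed: int = 0,
) -> MTLModel:
    """Fit the sparse multi-task model by monotone accelerated proximal gradient.

    Each iteration takes a gradient step on the smooth part (losses plus
    Frobenius term) from the extrapolated point, applies the closed-form
    soft-threshold prox for the L1 part with a backtracking line search,
    and falls back to the plain proximal step from the current iterate
    whenever the accelerated candidate would increase the objective, so
    accepted iterates never increase it.  Convergence is declared when
    the relative objective change drops below ``config.tol``;
    non-convergence at ``max_iter`` sets ``converged=False`` on the
    model (a warning, not an exception).

    Initialization is W = 0 (deterministic); ``seed`` is accepted for
    interface uniformity.
    """
    config = config or MTLConfig()
    if not tasks:
        raise ContractError("need at least one task")
    if lambda1 < 0 or lambda2 < 0:
        raise ContractError("penalty weights must be non-negative")
    p = tasks[0].X.shape[1]
    for t in tasks:
        if t.X.shape[1] != p:
            raise ContractError("all tasks must share the feature dimension")

    Xs, std_mean, std_scale = _design_matrices(tasks, config)
    Ys = [t.Y for t in tasks]
    p_total = p + (1 if config.add_bias else 0)
    n_tasks = len(tasks)
    mask = _penalty_mask(p_total, config.add_bias)

    def objective(W: np.ndarray) -> float:
        value, _ = _smooth_value_grad(W, Xs, Ys, lambda2, config.mean_loss)
        return value + lambda1 * float(np.abs(W[mask]).sum())

    W = np.zeros((p_total, n_tasks))
    V = W.copy()  # extrapolated point
    t_momentum = 1.0
    step = 1.0
    F = objective(W)
    history = [F]
    converged = False
    n_iter = 0

    for n_iter in range(1, config.max_iter + 1):
        f_v, grad_v = _smooth_value_grad(V, Xs, Ys, lambda2, config.mean_loss)
        # backtracking: shrink step until the quadratic model majorizes
        while True:
            Z = _prox(V - step * grad_v, step * lambda1, mask)
            diff = Z - V
            f_z, _ = _smooth_value_grad(Z, Xs, Ys, lambda2, config.mean_loss)
            quad = f_v + float((grad_v * diff).sum()) + float((diff ** 2).sum()) / (2 * step)
            if f_z <= quad + 1e-12:
                break
            step *= 0.5
            if step < 1e-16:
                break
        F_z = f_z + lambda1 * float(np.abs(Z[mask]).sum())
        # first-order stationarity: prox-gradient mapping at the
        # extrapolated point, sup-norm (before V is advanced)
        grad_map = np.abs(V - Z).max() / step

        if F_z <= F:  # accept the accelerated candidate
            W_next, F_next = Z, F_z
        else:  # monotone fallback: plain proximal step from W
            f_w, grad_w = _smooth_value_grad(W, Xs, Ys, lambda2, config.mean_loss)
            fallback_step = step
            while True:
                Z2 = _prox(W - fallback_step * grad_w, fallback_step * lambda1, mask)
                diff = Z2 - W
                f_z2, _ = _smooth_value_grad(Z2, Xs, Ys, lambda2, config.mean_loss)
                quad = f_w + float((grad_w * diff).sum()) + float((diff ** 2).sum()) / (2 * fallback_step)
                if f_z2 <= quad + 1e-12:
                    break
                fallback_step *= 0.5
                if fallback_step < 1e-16:
                    break
            F_z2 = f_z2 + lambda1 * float(np.abs(Z2[mask]).sum())
            W_next, F_next = (Z2, F_z2) if F_z2 <= F else (W, F)

        t_next = (1.0 + math.sqrt(1.0 + 4.0 * t_momentum ** 2)) / 2.0
        V = W_next + (t_momentum / t_next) * (Z - W_next) \
            + ((t_momentum - 1.0) / t_next) * (W_next - W)
        t_momentum = t_next

        rel_change = abs(F - F_next) / max(abs(F), 1.0)
        W, F = W_next, F_next
        history.append(F)
        if rel_change < config.tol and grad_map < config.gtol:
            converged = True
            break
        step *= 2.0  # allow the step to grow back between iterations

    if not converged:
        warnings.warn(
            f"proximal gradient did not converge in {config.max_iter} iterations",
            RuntimeWarning,
            stacklevel=2,
        )

    if feature_order is None:
        feature_order = tuple(f"feature_{j}" for j in range(p))
    names = tuple(feature_order) + (("bias",) if config.add_bias else ())
    return MTLModel(
        W=W,
        lambda1=lambda1,
        lambda2=lambda2,
        task_names=tuple(t.task_name for t in tasks),
        feature_order=names,
        config=config,
        converged=converged,
        n_iter=n_iter,
        objective_history=history,
        standardize_mean=std_mean,
        standardize_scale=std_scale,
    )


def lambda1_max(
    tasks: Sequence[TaskDataset],
    lambda2: float = DEFAULT_LAMBDA2,
    config: MTLConfig | None = None,
) -> float:
    """Smallest L1 weight at which the penalized coefficients are all zero.

    This is the max absolute entry of the smooth-part gradient over
    penalized coordinates at W = 0 (with an intercept enabled, the
    intercept block is first optimized with the penalized block frozen
    at zero).
    """
    config = config or MTLConfig()
    Xs, _, _ = _design_matrices(tasks, config)
    Ys = [t.Y for t in tasks]
    p_total = Xs[0].shape[1]
    W = np.zeros((p_total, len(tasks)))
    if config.add_bias:
        # fit the intercept row alone by a few Newton steps per task
        for i, (X, Y) in enumerate(zip(Xs, Ys)):
            b = 0.0
            for _ in range(50):
                prob = sigmoid(b * np.ones(len(Y)))
                # gradient/hessian of mean log-loss wrt intercept (labels +/-1)
                g = float(np.mean(prob - (Y + 1) / 2)) + 2 * lambda2 * b
                h = float(np.mean(prob * (1 - prob))) + 2 * lambda2
                if abs(g) < 1e-12:
                    break
                b -= g / h
            W[-1, i] = b
    _, grad = _smooth_value_grad(W, Xs, Ys, lambda2, config.mean_loss)
    mask = _penalty_mask(p_total, config.add_bias)
    return float(np.abs(grad[mask]).max())


def _pooled_fold_auc(
    model: MTLModel, held_out: Sequence[TaskDataset]
) -> float:
    scores: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    for t in held_out:
        if len(t.Y) == 0:
            continue
        scores.append(predict_probability(model, t.X, t.task_name))
        labels.append(t.Y > 0)
    if not scores:
        return float("nan")
    return roc_auc(np.concatenate(scores), np.concatenate(labels))


def cv_select_lambda1(
    tasks: Sequence[TaskDataset],
    lambda2: float,
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    folds: int = 10,
    seed: int = 0,
    config: MTLConfig | None = None,
    rule: str = "1se",
) -> float:
    """Pick lambda1 by stratified k-fold CV on pooled held-out AUC.

    Folds are stratified within each task; for every fold one model is
    fit per grid value on the remaining data and held-out predictions
    are pooled across tasks into a single AUC.  Folds where the pooled
    held-out labels are single-class are skipped with a warning.

    ``rule='max'`` returns the grid value maximizing the mean AUC (ties
    to the smaller value).  The default ``rule='1se'`` applies the
    one-standard-error rule: the largest (sparsest) grid value whose
    mean AUC is within one standard error of the maximum.  The
    AUC-maximizing penalty systematically under-penalizes — held-out
    ranking is almost insensitive to small coefficients on noise
    features — so the parsimonious rule is the shipped default for a
    model whose point is a sparse shared support.
    """
    if not grid:
        raise ContractError("lambda1 grid must be non-empty")
    if rule not in ("max", "1se"):
        raise ContractError("rule must be 'max' or '1se'")
    grid = sorted(set(float(g) for g in grid))
    if len(grid) == 1:
        return grid[0]
    config = config or MTLConfig()

    splitters = [
        list(
            StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed).split(
                t.X, t.Y
            )
        )
        for t in tasks
    ]
    fold_aucs: list[list[float]] = [[] for _ in grid]
    for k in range(folds):
        train_tasks, valid_tasks = [], []
        for t, splits in zip(tasks, splitters):
            train_idx, valid_idx = splits[k]
            train_tasks.append(
                TaskDataset(t.task_name, t.X[train_idx], t.Y[train_idx])
            )
            valid_tasks.append(
                TaskDataset(t.task_name, t.X[valid_idx], t.Y[valid_idx])
            )
        pooled_labels = np.concatenate([t.Y for t in valid_tasks])
        if len(np.unique(pooled_labels)) < 2:
            logger.warning("fold %d skipped: held-out labels single-class", k)
            continue
        for j, lam in enumerate(grid):
            model = fit_mtl(train_tasks, lam, lambda2, config=config)
            fold_aucs[j].append(_pooled_fold_auc(model, valid_tasks))
    if not fold_aucs[0]:
        raise ContractError("every CV fold was degenerate")
    means = np.array([np.mean(a) for a in fold_aucs])
    best = int(np.argmax(means))  # argmax takes the first (smallest) on ties
    if rule == "max":
        return grid[best]
    se = float(np.std(fold_aucs[best], ddof=1) / np.sqrt(len(fold_aucs[best])))
    eligible = [g for g, m in zip(grid, means) if m >= means[best] - se]
    return max(eligible)


def select_lambda2_on_validation(
    tasks_train: Sequence[TaskDataset],
    tasks_valid: Sequence[TaskDataset],
    grid: Sequence[float] = DEFAULT_LAMBDA_GRID,
    lambda1: float = DEFAULT_LAMBDA1,
    config: MTLConfig | None = None,
) -> float:
    """Pick lambda2 maximizing pooled AUC on held-out validation tasks.

    Ties (including degenerate constant predictions, which give NaN
    AUC treated as -inf) go to the smaller lambda2.
    """
    if not tasks_valid or all(t.n == 0 for t in tasks_valid):
        raise ContractError("validation tasks must be non-empty")
    grid = sorted(set(float(g) for g in grid))
    if len(grid) == 1:
        return grid[0]
    config = config or MTLConfig()
    best_lam, best_auc = grid[0], -np.inf
    for lam in grid:
        model = fit_mtl(tasks_train, lambda1, lam, config=config)
        auc = _pooled_fold_auc(model, tasks_valid)
        if math.isnan(auc):
            auc = -np.inf
        if auc > best_auc:  # strict: ties keep the earlier, smaller lambda2
            best_lam, best_auc = lam, auc
    return best_lam


def predict_probability(
    model: MTLModel, features: np.ndarray, task_name: str
) -> np.ndarray:
    """Per-gene driver probability sigmoid(X W_i) for one task."""
    i = model.task_index(task_name)
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if model.standardize_mean is not None:
        X = (X - model.standardize_mean) / model.standardize_scale
    if model.config.add_bias:
        X = np.hstack([X, np.ones((len(X), 1))])
    if X.shape[1] != model.W.shape[0]:
        raise ContractError(
            f"feature dimension {X.shape[1]} does not match model ({model.W.shape[0]})"
        )
    return sigmoid(X @ model.W[:, i])


def _threshold_candidates(probs: np.ndarray) -> np.ndarray:
    """Candidate cutoffs: 0, 1, the unique probabilities and their midpoints."""
    uniq = np.unique(probs)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    return np.unique(np.concatenate([[0.0, 1.0], uniq, mids]))


def select_task_thresholds(
    model: MTLModel, validation_tasks: Sequence[TaskDataset]
) -> dict[str, float]:
    """Per-task probability cutoffs maximizing validation accuracy.

    Candidates are the sorted unique predicted probabilities, the
    midpoints between consecutive ones, and the endpoints 0 and 1; ties
    are broken toward the larger threshold (fewer predicted drivers).
    Tasks without validation data default to 0.5 with a warning.
    """
    by_name = {t.task_name: t for t in validation_tasks}
    thresholds: dict[str, float] = {}
    for name in model.task_names:
        task = by_name.get(name)
        if task is None or task.n == 0:
            warnings.warn(
                f"no validation data for task '{name}'; threshold defaults to 0.5",
                RuntimeWarning,
                stacklevel=2,
            )
            thresholds[name] = 0.5
            continue
        probs = predict_probability(model, task.X, name)
        truth = task.Y > 0
        best_thr, best_acc = 0.5, -1.0
        for thr in _threshold_candidates(probs):
            acc = float(np.mean((probs >= thr) == truth))
            if acc > best_acc or (acc == best_acc and thr > best_thr):
                best_thr, best_acc = float(thr), acc
        thresholds[name] = best_thr
    model.thresholds = thresholds
    return thresholds


def save_mtl_model(model: MTLModel, path: str) -> None:
    """Serialize the fitted model (JSON: W, penalties, thresholds, metadata)."""
    import json

    payload = {
        "artifact_version": 1,
        "W": model.W.tolist(),
        "lambda1": model.lambda1,
        "lambda2": model.lambda2,
        "task_names": list(model.task_names),
        "feature_order": list(model.feature_order),
        "thresholds": model.thresholds,
        "converged": model.converged,
        "n_iter": model.n_iter,
        "config": {
            "add_bias": model.config.add_bias,
            "mean_loss": model.config.mean_loss,
            "standardize": model.config.standardize,
            "max_iter": model.config.max_iter,
            "tol": model.config.tol,
        },
        "standardize_mean": None
        if model.standardize_mean is None
        else model.standardize_mean.tolist(),
        "standardize_scale": None
        if model.standardize_scale is None
        else model.standardize_scale.tolist(),
    }
    with open(path, "w") as handle:
        json.dump(payload, handle, indent=1)


def load_mtl_model(path: str) -> MTLModel:
    import json

    with open(path) as handle:
        payload = json.load(handle)
    if payload.get("artifact_version") != 1:
        raise ContractError("unsupported model artifact version")
    return MTLModel(
        W=np.asarray(payload["W"], dtype=float),
        lambda1=payload["lambda1"],
        lambda2=payload["lambda2"],
        task_names=tuple(payload["task_names"]),
        feature_order=tuple(payload["feature_order"]),
        config=MTLConfig(**payload["config"]),
        thresholds=dict(payload["thresholds"]),
        converged=payload["converged"],
        n_iter=payload["n_iter"],
        standardize_mean=None
        if payload["standardize_mean"] is None
        else np.asarray(payload["standardize_mean"]),
        standardize_scale=None
        if payload["standardize_scale"] is None
        else np.asarray(payload["standardize_scale"]),
    )


def classify_drivers(
    probabilities: np.ndarray, threshold: float
) -> np.ndarray:
    """Label genes driver/non_driver; the boundary is inclusive (>=)."""
    if not 0 <= threshold <= 1:
        raise ContractError("threshold must be in [0, 1]")
    probs = np.asarray(probabilities, dtype=float)
    return np.where(probs >= threshold, "driver", "non_driver")
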