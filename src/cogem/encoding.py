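"""Region-wise ridge encoding models with nested cross-validation.

The encoding model is a linear map from ontological feature space to
region-level activation: for every cortical region r, weights w_r minimize

    || y_r - X w_r - b_r ||^2 + alpha ||w_r||^2

with an unpenalized intercept b_r, implemented by centering the design
columns and responses, solving the penalized normal equations for all
regions at once, and recovering the intercepts. Features stay on their
native [0, 1] annotation scale (no further standardization).

Generalization is estimated with leave-two-out cross-validation over tasks:
for each of the C(n, 2) task pairs, models are trained on the session rows
of the remaining n-2 tasks, the regularization strength is chosen by an
inner k-fold cross-validation *grouped by task* (so a task's 2-4 session
rows never straddle the inner train/validation boundary), and the held-out
tasks' maps are predicted and scored by the evaluation module.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .datasets import SubjectData
from .evaluation import (
    SplitResult,
    map_r2,
    session_avg_corr,
    two_way_classify,
)
from .features import FeatureMatrix

#: Regularization strengths searched by the inner cross-validation loop.
DEFAULT_ALPHA_GRID = (0.001, 0.01, 0.1, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0,
                      8.0, 9.0, 10.0)


def validate_alpha_grid(grid) -> tuple[float, ...]:
    grid = tuple(float(a) for a in grid)
    if not grid:
        raise ValueError("alpha grid is empty")
    if any(a <= 0 for a in grid):
        raise ValueError("alpha values must be positive")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("alpha grid must be strictly increasing")
    return grid


@dataclass
class CEMFit:
    """Fitted region-wise encoding models for one training set."""

    weights: np.ndarray      # (n_features, n_regions)
    intercepts: np.ndarray   # (n_regions,)
    alpha: float
    training_tasks: list[str]
    feature_ids: list[str]


def _as_design(X):
    """Accept a DesignMatrix or a plain array; return (values, task_of_row)."""
    if hasattr(X, "values") and hasattr(X, "task_of_row"):
        return np.asarray(X.values, dtype=float), np.asarray(X.task_of_row)
    return np.asarray(X, dtype=float), None


def fit_ridge(
    X,
    Y: np.ndarray,
    alpha: float,
    feature_ids: list[str] | None = None,
    training_tasks: list[str] | None = None,
) -> CEMFit:
    """Closed-form ridge fit with unpenalized intercepts, all regions jointly."""
    Xv, _ = _as_design(X)
    Y = np.asarray(Y, dtype=float)
    if Xv.ndim != 2 or Y.ndim != 2 or Xv.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching row counts")
    if Xv.shape[0] == 0:
        raise ValueError("cannot fit with zero rows")
    if not (np.isfinite(Xv).all() and np.isfinite(Y).all()):
        raise ValueError("non-finite values in X or Y")
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    xm = Xv.mean(axis=0)
    ym = Y.mean(axis=0)
    Xc = Xv - xm
    A = Xc.T @ Xc + alpha * np.eye(Xv.shape[1])
    W = np.linalg.solve(A, Xc.T @ (Y - ym))
    b = ym - xm @ W
    return CEMFit(
        weights=W,
        intercepts=b,
        alpha=float(alpha),
        training_tasks=list(training_tasks or []),
        feature_ids=list(feature_ids or []),
    )


def predict_map(fit: CEMFit, feature_vector: np.ndarray) -> np.ndarray:
    """Predicted per-region activation for one feature vector (affine map)."""
    fv = np.asarray(feature_vector, dtype=float)
    if fv.shape != (fit.weights.shape[0],):
        raise ValueError(
            f"feature vector length {fv.shape} does not match "
            f"{fit.weights.shape[0]} model features"
        )
    return fv @ fit.weights + fit.intercepts


def predict_maps(fit: CEMFit, feature_matrix: np.ndarray) -> np.ndarray:
    """Row-wise :func:`predict_map` for a (tasks x features) matrix."""
    F = np.asarray(feature_matrix, dtype=float)
    if F.shape[1] != fit.weights.shape[0]:
        raise ValueError("feature matrix width does not match model features")
    return F @ fit.weights + fit.intercepts


def leave_two_out_splits(task_ids) -> list[tuple[str, str]]:
    """All C(n, 2) unordered task pairs, in deterministic lexicographic order
    of the input task sequence."""
    task_ids = list(task_ids)
    if len(task_ids) < 3:
        raise ValueError("leave-two-out needs at least 3 tasks")
    return list(combinations(task_ids, 2))


def select_alpha(
    X,
    Y: np.ndarray,
    grid=DEFAULT_ALPHA_GRID,
    k: int = 10,
    rng=None,
    task_of_row: np.ndarray | None = None,
) -> float:
    """Choose the ridge penalty by inner k-fold CV grouped by task.

    Tasks (not rows) are partitioned into ``k`` folds; for each candidate
    alpha the model is fit on k-1 folds and scored on the held-out rows as
    the mean Pearson correlation between predicted and observed region maps.
    The alpha maximizing the mean score is returned; exact ties (including
    the all-undefined case of constant maps) go to the smallest alpha.
    """
    grid = validate_alpha_grid(grid)
    Xv, tor = _as_design(X)
    if task_of_row is not None:
        tor = np.asarray(task_of_row)
    if tor is None:
        raise ValueError("task grouping of rows is required (task_of_row)")
    Y = np.asarray(Y, dtype=float)
    tasks = list(dict.fromkeys(tor))
    if len(grid) == 1:
        return grid[0]
    if len(tasks) < k:
        raise ValueError(f"{len(tasks)} tasks is fewer than {k} inner folds")
    rng = np.random.default_rng(rng)
    order = rng.permutation(len(tasks))
    folds = np.array_split(order, k)

    scores = np.zeros(len(grid))
    counts = np.zeros(len(grid))
    eye = np.eye(Xv.shape[1])
    for fold in folds:
        val_tasks = {tasks[i] for i in fold}
        val_mask = np.array([t in val_tasks for t in tor])
        Xtr, Ytr = Xv[~val_mask], Y[~val_mask]
        xm, ym = Xtr.mean(axis=0), Ytr.mean(axis=0)
        Xc = Xtr - xm
        G = Xc.T @ Xc
        C = Xc.T @ (Ytr - ym)
        Xval = Xv[val_mask] - xm
        for gi, alpha in enumerate(grid):
            W = np.linalg.solve(G + alpha * eye, C)
            pred = Xval @ W + ym
            for row_pred, row_obs in zip(pred, Y[val_mask]):
                r = _safe_r(row_pred, row_obs)
                if not np.isnan(r):
                    scores[gi] += r
                    counts[gi] += 1
    with np.errstate(invalid="ignore"):
        mean_scores = np.where(counts > 0, scores / np.maximum(counts, 1),
                               -np.inf)
    if not np.isfinite(mean_scores).any():
        return grid[0]
    best = 0
    for gi in range(1, len(grid)):
        if mean_scores[gi] > mean_scores[best]:
            best = gi
    return grid[best]


def _safe_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r returning NaN (instead of raising) on zero variance; used
    only for inner-CV scoring where undefined rows are skipped."""
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float((xc @ yc) / denom)


def _stack_subject(subject: SubjectData, fm: FeatureMatrix):
    """Stacked session-level design and response arrays for one subject."""
    if set(subject.task_ids) != set(fm.task_ids):
        raise ValueError("subject tasks do not match feature matrix tasks")
    X_rows, Y_rows, tasks = [], [], []
    for i, task in enumerate(fm.task_ids):
        maps = subject.maps[task]
        X_rows.append(np.tile(fm.values[i], (maps.shape[0], 1)))
        Y_rows.append(maps)
        tasks.extend([task] * maps.shape[0])
    return (
        np.vstack(X_rows),
        np.vstack(Y_rows),
        np.array(tasks, dtype=object),
    )


def run_subject_cv(
    subject: SubjectData,
    fm: FeatureMatrix,
    grid=DEFAULT_ALPHA_GRID,
    inner_k: int = 10,
    rng=None,
    store_predictions: bool = False,
) -> list[SplitResult]:
    """Full leave-two-out evaluation of one subject's encoding models.

    For every task pair: all session rows of both held-out tasks are removed
    from training (asserted structurally), alpha is selected on the
    remaining tasks by :func:`select_alpha`, region-wise models are fit at
    that alpha, and each held-out task's map is predicted from its feature
    vector and scored (session-averaged r, R^2, two-way classification).
    """
    grid = validate_alpha_grid(grid)
    rng = np.random.default_rng(rng)
    X_all, Y_all, task_of_row = _stack_subject(subject, fm)
    results = []
    for task_a, task_b in leave_two_out_splits(fm.task_ids):
        held = {task_a, task_b}
        train_mask = np.array([t not in held for t in task_of_row])
        assert not set(task_of_row[train_mask]) & held  # no-leakage guard
        Xtr, Ytr = X_all[train_mask], Y_all[train_mask]
        alpha = select_alpha(
            Xtr, Ytr, grid=grid, k=inner_k, rng=rng,
            task_of_row=task_of_row[train_mask],
        )
        training_tasks = [t for t in fm.task_ids if t not in held]
        fit = fit_ridge(Xtr, Ytr, alpha, feature_ids=fm.feature_ids,
                        training_tasks=training_tasks)
        pred_a = predict_map(fit, fm.task_vector(task_a))
        pred_b = predict_map(fit, fm.task_vector(task_b))
        obs_a = subject.maps[task_a]
        obs_b = subject.maps[task_b]
        assignment, correct, tied = two_way_classify(
            pred_a, pred_b, obs_a, obs_b, labels=(task_a, task_b)
        )
        results.append(
            SplitResult(
                subject=subject.subject,
                tasks=(task_a, task_b),
                alpha=alpha,
                r={
                    task_a: session_avg_corr(pred_a, obs_a),
                    task_b: session_avg_corr(pred_b, obs_b),
                },
                r2={
                    task_a: map_r2(pred_a, obs_a),
                    task_b: map_r2(pred_b, obs_b),
                },
                assignment=assignment,
                correct=correct,
                tied=tied,
                predictions=(
                    {task_a: pred_a, task_b: pred_b} if store_predictions
                    else None
                ),
            )
        )
    return results
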