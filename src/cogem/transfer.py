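"""Between-subject generalization of encoding models.

Each source subject's models are trained once on all of their tasks (alpha
chosen by the same inner k-fold procedure) and then evaluated on every
target subject: the source model predicts all task maps, and two-way
classification is run for every task pair against the target's observed
session maps. The diagonal of the resulting source x target accuracy matrix
is self-transfer, computed identically to the off-diagonal cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import ActivationDataset, SubjectData
from .encoding import (
    DEFAULT_ALPHA_GRID,
    CEMFit,
    _stack_subject,
    fit_ridge,
    leave_two_out_splits,
    predict_maps,
    select_alpha,
)
from .features import FeatureMatrix


def fit_full(
    subject: SubjectData,
    fm: FeatureMatrix,
    grid=DEFAULT_ALPHA_GRID,
    inner_k: int = 10,
    rng=None,
) -> CEMFit:
    """Fit one subject's encoding models on all session rows of all tasks."""
    rng = np.random.default_rng(rng)
    X, Y, task_of_row = _stack_subject(subject, fm)
    alpha = select_alpha(X, Y, grid=grid, k=inner_k, rng=rng,
                         task_of_row=task_of_row)
    return fit_ridge(X, Y, alpha, feature_ids=fm.feature_ids,
                     training_tasks=list(fm.task_ids))


def _session_avg_corr_matrix(
    preds: np.ndarray, subject: SubjectData, task_ids: list[str]
) -> np.ndarray:
    """C[i, j] = session-averaged Pearson r between predicted map of task i
    and the observed session maps of task j."""
    sessions = []
    owner = []
    for j, task in enumerate(task_ids):
        for m in subject.maps[task]:
            sessions.append(m)
            owner.append(j)
    S = np.vstack(sessions)
    owner = np.asarray(owner)

    def _rows_normalize(M):
        Mc = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(Mc, axis=1, keepdims=True)
        if (norms == 0).any():
            raise ValueError("correlation undefined for a zero-variance map")
        return Mc / norms

    R = _rows_normalize(preds) @ _rows_normalize(S).T  # (tasks, sessions)
    C = np.empty((len(task_ids), len(task_ids)))
    for j in range(len(task_ids)):
        C[:, j] = R[:, owner == j].mean(axis=1)
    return C


@dataclass
class TransferResult:
    """Source x target accuracy and mean-correlation matrices."""

    accuracy: pd.DataFrame
    correlation: pd.DataFrame

    @property
    def self_transfer(self) -> pd.Series:
        return pd.Series(np.diag(self.accuracy), index=self.accuracy.index)

    @property
    def cross_transfer_mean(self) -> float:
        a = self.accuracy.to_numpy()
        mask = ~np.eye(a.shape[0], dtype=bool)
        return float(a[mask].mean())


def transfer_evaluate(
    fits: dict[str, CEMFit],
    dataset: ActivationDataset,
    fm: FeatureMatrix,
) -> TransferResult:
    """Evaluate every source subject's full fit on every target subject.

    Cell (source, target) of ``accuracy`` is the fraction of task pairs for
    which both of the source model's predicted maps are assigned to their
    own tasks by the two-way classifier (ties broken toward the pair's first
    task, as in the within-subject scheme); ``correlation`` holds the mean
    over tasks of the predicted-observed session-averaged correlation.
    """
    task_ids = list(fm.task_ids)
    pairs = leave_two_out_splits(task_ids)
    pair_idx = [(task_ids.index(a), task_ids.index(b)) for a, b in pairs]
    sources = list(fits)
    targets = dataset.subject_ids
    acc = np.empty((len(sources), len(targets)))
    corr = np.empty_like(acc)
    for si, src in enumerate(sources):
        preds = predict_maps(fits[src], fm.values)
        for ti, tgt in enumerate(targets):
            C = _session_avg_corr_matrix(preds, dataset.subject(tgt), task_ids)
            n_correct = 0
            for i, j in pair_idx:
                # pred_i tie -> first task (correct); pred_j tie -> first task
                correct = C[i, i] >= C[i, j] and C[j, j] > C[j, i]
                n_correct += correct
            acc[si, ti] = n_correct / len(pair_idx)
            corr[si, ti] = float(np.mean(np.diag(C)))
    return TransferResult(
        accuracy=pd.DataFrame(acc, index=sources, columns=targets),
        correlation=pd.DataFrame(corr, index=sources, columns=targets),
    )
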