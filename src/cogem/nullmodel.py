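"""Task-shuffled permutation null model.

Each iteration bijectively remaps tasks to one another and replaces every
task's feature vector with its donor's before re-running the complete
nested-CV pipeline. Because a task's 2-4 session rows all receive the
donor's vector, task blocks are preserved while column densities are not
(a 2-session task's vector can occupy 4 design rows after shuffling).
The global identity permutation is excluded; individual fixed points are
allowed unless full derangements are requested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datasets import SubjectData
from .encoding import DEFAULT_ALPHA_GRID, run_subject_cv
from .evaluation import SplitResult, aggregate_metrics, subject_accuracy
from .features import FeatureMatrix


@dataclass(frozen=True)
class TaskPermutation:
    """A bijective task -> donor-task remapping, tagged for reproducibility."""

    mapping: tuple[tuple[str, str], ...]
    seed: int | None = None
    iteration: int = 0

    def __post_init__(self) -> None:
        src = [a for a, _ in self.mapping]
        dst = [b for _, b in self.mapping]
        if set(src) != set(dst) or len(set(src)) != len(src):
            raise ValueError("mapping must be a bijection over the task set")

    def as_dict(self) -> dict[str, str]:
        return dict(self.mapping)


def permutation_for(
    task_ids,
    seed: int,
    iteration: int,
    forbid_fixed_points: bool = False,
) -> TaskPermutation:
    """The permutation used at a given (seed, iteration) — reconstructible."""
    rng = np.random.default_rng([int(seed), int(iteration)])
    return sample_permutation(
        task_ids, rng, forbid_fixed_points=forbid_fixed_points,
        seed=seed, iteration=iteration,
    )


def sample_permutation(
    task_ids,
    rng,
    forbid_fixed_points: bool = False,
    seed: int | None = None,
    iteration: int = 0,
) -> TaskPermutation:
    """Uniform random permutation of tasks, excluding the global identity.

    With ``forbid_fixed_points`` the sample is restricted to derangements
    (no task keeps its own feature vector).
    """
    task_ids = list(task_ids)
    if len(task_ids) < 2:
        raise ValueError("need at least 2 tasks to permute")
    while True:
        perm = rng.permutation(len(task_ids))
        if (perm == np.arange(len(task_ids))).all():
            continue
        if forbid_fixed_points and (perm == np.arange(len(task_ids))).any():
            continue
        break
    mapping = tuple(
        (task_ids[i], task_ids[perm[i]]) for i in range(len(task_ids))
    )
    return TaskPermutation(mapping=mapping, seed=seed, iteration=iteration)


def shuffle_features(fm: FeatureMatrix, perm: TaskPermutation) -> FeatureMatrix:
    """Replace each task's feature vector with its donor's; task order,
    ids and session structure are untouched."""
    mapping = perm.as_dict()
    if set(mapping) != set(fm.task_ids):
        raise ValueError("permutation does not cover the task set")
    donor_rows = np.array(
        [fm.task_index(mapping[t]) for t in fm.task_ids], dtype=int
    )
    return FeatureMatrix(
        task_ids=list(fm.task_ids),
        feature_ids=list(fm.feature_ids),
        values=fm.values[donor_rows],
        feature_class=fm.feature_class.copy(),
        parametric=fm.parametric.copy(),
    )


@dataclass
class NullResult:
    """Per-iteration and averaged null-model metrics for one subject."""

    subject: str
    per_iteration: pd.DataFrame
    permutations: list[TaskPermutation]

    @property
    def mean_metrics(self) -> pd.Series:
        return self.per_iteration[["accuracy", "mean_r", "mean_r2"]].mean()


def run_null(
    subject: SubjectData,
    fm: FeatureMatrix,
    grid=DEFAULT_ALPHA_GRID,
    n_iter: int = 20,
    seed: int = 0,
    inner_k: int = 10,
    forbid_fixed_points: bool = False,
    permutations: list[TaskPermutation] | None = None,
) -> NullResult:
    """Task-shuffled null for one subject, averaged over ``n_iter`` iterations.

    Each iteration's permutation derives only from (seed, iteration) via
    :func:`permutation_for`, so the permutation log is reconstructible.
    Explicit ``permutations`` may be supplied instead (e.g. to force the
    identity and recover the unshuffled pipeline).
    """
    if permutations is None:
        permutations = [
            permutation_for(fm.task_ids, seed, it, forbid_fixed_points)
            for it in range(n_iter)
        ]
    rows = []
    for it, perm in enumerate(permutations):
        shuffled = shuffle_features(fm, perm)
        cv_rng = np.random.default_rng([int(seed), int(it), 1])
        splits: list[SplitResult] = run_subject_cv(
            subject, shuffled, grid=grid, inner_k=inner_k, rng=cv_rng
        )
        per_subject, _ = aggregate_metrics(splits)
        rows.append(
            {
                "iteration": it,
                "accuracy": subject_accuracy(splits),
                "mean_r": float(per_subject["mean_r"].iloc[0]),
                "mean_r2": float(per_subject["mean_r2"].iloc[0]),
            }
        )
    return NullResult(
        subject=subject.subject,
        per_iteration=pd.DataFrame(rows),
        permutations=list(permutations),
    )
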