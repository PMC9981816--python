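"""Ontological feature matrices and session-level design expansion.

Tasks are annotated with features drawn from a cognitive ontology: mostly
binary indicators of engaged psychological functions, plus a small number of
parametric features (e.g. number of response alternatives, number of left- or
right-hand responses per block) whose raw magnitudes are recoded to dense
rank indices scaled to [0, 1].  Each feature carries a class label —
Cognitive (``"C"``) or Perceptual-Motor (``"PM"``) — so models can be fit on
the full feature space or on either half.

Because each task's activation is measured in two or four imaging sessions,
the task-level feature matrix is expanded to a session-level design matrix in
which every task contributes one identical row per session.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CLASS_COGNITIVE = "C"
CLASS_PERCEPTUAL_MOTOR = "PM"
VALID_CLASSES = (CLASS_COGNITIVE, CLASS_PERCEPTUAL_MOTOR)
VALID_SESSION_COUNTS = (2, 4)


@dataclass
class FeatureMatrix:
    """A task-by-feature annotation matrix with per-feature metadata.

    Parameters
    ----------
    task_ids : list of str
        Unique, ordered task labels (rows).
    feature_ids : list of str
        Unique, ordered feature labels (columns).
    values : ndarray of shape (n_tasks, n_features)
        Annotation values, all in [0, 1].
    feature_class : ndarray of str
        Per-feature class, each ``"C"`` or ``"PM"``.
    parametric : ndarray of bool
        Per-feature flag marking parametrically coded features.
    """

    task_ids: list[str]
    feature_ids: list[str]
    values: np.ndarray
    feature_class: np.ndarray
    parametric: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.feature_class = np.asarray(self.feature_class, dtype=object)
        self.parametric = np.asarray(self.parametric, dtype=bool)
        if len(set(self.task_ids)) != len(self.task_ids):
            raise ValueError("task_ids must be unique")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.values.shape != (len(self.task_ids), len(self.feature_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.task_ids)} tasks x {len(self.feature_ids)} features"
            )
        if self.values.size and (self.values.min() < 0 or self.values.max() > 1):
            raise ValueError("feature values must lie in [0, 1]")
        if self.feature_class.shape != (len(self.feature_ids),):
            raise ValueError("feature_class must have one entry per feature")
        if self.parametric.shape != (len(self.feature_ids),):
            raise ValueError("parametric must have one entry per feature")
        bad = set(self.feature_class) - set(VALID_CLASSES)
        if bad:
            raise ValueError(f"invalid feature classes: {sorted(bad)}")

    @property
    def n_tasks(self) -> int:
        return len(self.task_ids)

    @property
    def n_features(self) -> int:
        return len(self.feature_ids)

    def task_index(self, task: str) -> int:
        return self.task_ids.index(task)

    def task_vector(self, task: str) -> np.ndarray:
        return self.values[self.task_index(task)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.task_ids, columns=self.feature_ids)


@dataclass
class DesignMatrix:
    """Session-level expansion of a :class:`FeatureMatrix`.

    Each task contributes one row per imaging session; rows of the same task
    are contiguous and carry identical feature vectors.
    """

    rows: list[tuple[str, int]]
    values: np.ndarray
    task_of_row: np.ndarray
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.task_of_row = np.asarray(self.task_of_row, dtype=object)
        if len(self.rows) != self.values.shape[0]:
            raise ValueError("row labels inconsistent with value matrix")
        if self.task_of_row.shape != (self.values.shape[0],):
            raise ValueError("task_of_row inconsistent with value matrix")
        # rows of one task must share a feature vector
        for task in dict.fromkeys(self.task_of_row):
            block = self.values[self.task_of_row == task]
            if block.shape[0] not in VALID_SESSION_COUNTS:
                raise ValueError(
                    f"task {task!r} has {block.shape[0]} rows; expected one of "
                    f"{VALID_SESSION_COUNTS}"
                )
            if not (block == block[0]).all():
                raise ValueError(f"rows of task {task!r} differ")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]


def recode_parametric(raw_levels) -> np.ndarray:
    """Recode raw parametric magnitudes as scaled dense-rank indices.

    Each value is replaced by the index of its raw magnitude among the sorted
    *distinct* magnitudes (so ties share a code), divided by the number of
    distinct magnitudes minus one.  The output therefore spans [0, 1] and
    preserves the order of the raw values.

    Raises
    ------
    ValueError
        If fewer than two distinct raw values are present (scaling would be
        undefined).
    """
    raw = np.asarray(raw_levels, dtype=float)
    if raw.ndim != 1:
        raise ValueError("raw_levels must be one-dimensional")
    distinct = np.unique(raw)
    if distinct.size < 2:
        raise ValueError("parametric recoding needs at least 2 distinct raw values")
    ranks = np.searchsorted(distinct, raw)
    return ranks / (distinct.size - 1)


def subset_features(fm: FeatureMatrix, which: str) -> FeatureMatrix:
    """Return the feature subset ``"all"``, ``"cognitive"`` or ``"perceptual_motor"``.

    ``"all"`` returns ``fm`` unchanged. Task order is always preserved.
    """
    key = which.strip().lower().replace("-", "_")
    if key == "all":
        return fm
    if key == "cognitive":
        mask = fm.feature_class == CLASS_COGNITIVE
    elif key in ("perceptual_motor", "pm"):
        mask = fm.feature_class == CLASS_PERCEPTUAL_MOTOR
    else:
        raise ValueError(f"unknown feature subset {which!r}")
    if not mask.any():
        raise ValueError(f"feature subset {which!r} is empty")
    idx = np.flatnonzero(mask)
    return FeatureMatrix(
        task_ids=list(fm.task_ids),
        feature_ids=[fm.feature_ids[i] for i in idx],
        values=fm.values[:, idx],
        feature_class=fm.feature_class[idx],
        parametric=fm.parametric[idx],
    )


def expand_to_sessions(fm: FeatureMatrix, session_counts: dict) -> DesignMatrix:
    """Expand a task-level feature matrix to one row per (task, session).

    ``session_counts`` maps every task id to 2 or 4. Rows are grouped
    contiguously by task, in the task order of ``fm``.
    """
    missing = [t for t in fm.task_ids if t not in session_counts]
    if missing:
        raise ValueError(f"missing session counts for tasks: {missing}")
    rows: list[tuple[str, int]] = []
    blocks = []
    tasks = []
    for i, task in enumerate(fm.task_ids):
        count = session_counts[task]
        if count not in VALID_SESSION_COUNTS:
            raise ValueError(
                f"session count for task {task!r} is {count}; must be one of "
                f"{VALID_SESSION_COUNTS}"
            )
        rows.extend((task, s) for s in range(count))
        blocks.append(np.tile(fm.values[i], (count, 1)))
        tasks.extend([task] * count)
    return DesignMatrix(
        rows=rows,
        values=np.vstack(blocks),
        task_of_row=np.array(tasks, dtype=object),
        feature_ids=list(fm.feature_ids),
    )


def write_feature_tsv(fm: FeatureMatrix, path) -> None:
    """Write the feature-matrix TSV dialect.

    Layout: header row of feature ids, a ``class`` row (C/PM), a
    ``parametric`` row (0/1), then one row of values per task.
    """
    with open(path, "w") as fh:
        fh.write("task\t" + "\t".join(fm.feature_ids) + "\n")
        fh.write("class\t" + "\t".join(fm.feature_class) + "\n")
        fh.write("parametric\t" + "\t".join(str(int(p)) for p in fm.parametric) + "\n")
        for i, task in enumerate(fm.task_ids):
            vals = "\t".join(format(v, ".10g") for v in fm.values[i])
            fh.write(f"{task}\t{vals}\n")


def read_feature_tsv(path) -> FeatureMatrix:
    """Read the TSV dialect written by :func:`write_feature_tsv`."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if "class" not in df.index or "parametric" not in df.index:
        raise ValueError("feature TSV must contain 'class' and 'parametric' rows")
    feature_class = df.loc["class"].to_numpy(dtype=object)
    parametric = df.loc["parametric"].astype(int).to_numpy(dtype=bool)
    body = df.drop(index=["class", "parametric"]).astype(float)
    return FeatureMatrix(
        task_ids=[str(t) for t in body.index],
        feature_ids=[str(c) for c in body.columns],
        values=body.to_numpy(),
        feature_class=feature_class,
        parametric=parametric,
    )
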