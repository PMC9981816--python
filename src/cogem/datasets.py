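"""In-memory containers and plain-text I/O for session-level activation data.

An :class:`ActivationDataset` holds, per subject, the two or four z-scored
activation maps (one per imaging session) measured for each task condition.
Sessions carry a timepoint label (scanning visit) so that between-session
reliability can be computed within timepoints, as required by the noise
ceiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class SubjectData:
    """All session-level activation maps for one subject.

    ``maps[task]`` has shape (n_sessions, n_regions); ``timepoints[task]``
    labels each session with its scanning visit (two-session tasks were
    acquired at one visit, four-session tasks at two).
    """

    subject: str
    task_ids: list[str]
    maps: dict[str, np.ndarray]
    timepoints: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        for task in self.task_ids:
            if task not in self.maps:
                raise ValueError(f"missing maps for task {task!r}")
            arr = np.asarray(self.maps[task], dtype=float)
            self.maps[task] = arr
            tp = tuple(self.timepoints.get(task, ()))
            if len(tp) != arr.shape[0]:
                raise ValueError(f"timepoint labels inconsistent for task {task!r}")

    @property
    def session_counts(self) -> dict[str, int]:
        return {t: self.maps[t].shape[0] for t in self.task_ids}

    @property
    def n_regions(self) -> int:
        return self.maps[self.task_ids[0]].shape[1]


@dataclass
class ActivationDataset:
    """Session-level activation maps for a cohort of subjects."""

    subjects: list[SubjectData]
    task_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("dataset needs at least one subject")
        if not self.task_ids:
            self.task_ids = list(self.subjects[0].task_ids)
        for sub in self.subjects:
            if list(sub.task_ids) != list(self.task_ids):
                raise ValueError(f"subject {sub.subject} task set differs")

    @property
    def n_regions(self) -> int:
        return self.subjects[0].n_regions

    @property
    def subject_ids(self) -> list[str]:
        return [s.subject for s in self.subjects]

    def subject(self, subject_id: str) -> SubjectData:
        for s in self.subjects:
            if s.subject == subject_id:
                return s
        raise KeyError(subject_id)


def to_long_frame(dataset: ActivationDataset) -> pd.DataFrame:
    """Flatten a dataset to long form: subject, task, session, timepoint, region, z."""
    records = []
    for sub in dataset.subjects:
        for task in sub.task_ids:
            arr = sub.maps[task]
            tps = sub.timepoints[task]
            for s in range(arr.shape[0]):
                records.append(
                    pd.DataFrame(
                        {
                            "subject": sub.subject,
                            "task": task,
                            "session": s,
                            "timepoint": tps[s],
                            "region": np.arange(arr.shape[1]),
                            "z": arr[s],
                        }
                    )
                )
    return pd.concat(records, ignore_index=True)


def write_activations_tsv(dataset: ActivationDataset, path) -> None:
    to_long_frame(dataset).to_csv(path, sep="\t", index=False)


def read_activations_tsv(path) -> ActivationDataset:
    df = pd.read_csv(path, sep="\t")
    subjects = []
    task_order = list(dict.fromkeys(df["task"]))
    for subject_id, sdf in df.groupby("subject", sort=False):
        maps = {}
        timepoints = {}
        for task, tdf in sdf.groupby("task", sort=False):
            sessions = sorted(tdf["session"].unique())
            rows = []
            tps = []
            for s in sessions:
                block = tdf[tdf["session"] == s].sort_values("region")
                rows.append(block["z"].to_numpy())
                tps.append(int(block["timepoint"].iloc[0]))
            maps[task] = np.vstack(rows)
            timepoints[task] = tuple(tps)
        subjects.append(
            SubjectData(
                subject=str(subject_id),
                task_ids=task_order,
                maps=maps,
                timepoints=timepoints,
            )
        )
    return ActivationDataset(subjects=subjects)


def write_network_labels(labels: np.ndarray, path) -> None:
    pd.DataFrame(
        {"region": np.arange(len(labels)), "network": labels}
    ).to_csv(path, sep="\t", index=False)


def read_network_labels(path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t").sort_values("region")
    return df["network"].to_numpy()
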