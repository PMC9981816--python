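"""Generalization metrics for cognitive encoding models.

Implements the evaluation scheme used with leave-two-out cross-validation:
session-averaged map-wise Pearson correlations and coefficients of
determination, the two-way correlation-based minimum-distance classifier
(chance level 25% because the two predicted maps are classified
independently), noise ceilings from between-session reliability, metric
aggregation, feature-set comparison statistics and the split-type breakdown
by meta-task overlap between train and test tasks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation with an explicit error on zero-variance input."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations for a correlation")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined for a zero-variance map")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class SplitResult:
    """Outcome of one leave-two-out split for one subject.

    ``assignment`` maps each held-out task (identifying its predicted map)
    to the task the classifier assigned that map to. ``correct`` is True only
    if both predicted maps were assigned to their own tasks.
    """

    subject: str
    tasks: tuple[str, str]
    alpha: float
    r: dict[str, float]
    r2: dict[str, float]
    assignment: dict[str, str]
    correct: bool
    tied: bool = False
    predictions: dict[str, np.ndarray] | None = None


def session_avg_corr(pred: np.ndarray, observed_sessions: np.ndarray) -> float:
    """Mean over sessions of the Pearson correlation between the predicted
    map and each observed session map."""
    obs = np.atleast_2d(np.asarray(observed_sessions, dtype=float))
    if obs.shape[0] < 1:
        raise ValueError("need at least one observed session map")
    return float(np.mean([pearson_r(pred, m) for m in obs]))


def map_r2(pred: np.ndarray, observed_sessions: np.ndarray) -> float:
    """Session-averaged coefficient of determination.

    Per session: ``1 - SS_res / SS_tot`` about the observed map's mean; can
    be negative when the prediction is worse than the observed mean.
    """
    pred = np.asarray(pred, dtype=float)
    obs = np.atleast_2d(np.asarray(observed_sessions, dtype=float))
    vals = []
    for m in obs:
        ss_tot = float(np.sum((m - m.mean()) ** 2))
        if ss_tot == 0:
            raise ValueError("R^2 undefined for a zero-variance observed map")
        vals.append(1.0 - float(np.sum((m - pred) ** 2)) / ss_tot)
    return float(np.mean(vals))


def two_way_classify(
    pred_a: np.ndarray,
    pred_b: np.ndarray,
    obs_a: np.ndarray,
    obs_b: np.ndarray,
    labels: tuple[str, str] = ("a", "b"),
) -> tuple[dict[str, str], bool, bool]:
    """Correlation-based minimum-distance classification of two predicted maps.

    Each predicted map is independently assigned to whichever of the two
    tasks yields the larger session-averaged correlation; the two decisions
    may both point to the same task (which forces ``correct=False`` — the
    mechanism behind below-chance null-model accuracy when predictions
    collapse onto the training mean). Exact ties are broken toward the first
    task and flagged.

    Returns ``(assignment, correct, tied)``.
    """
    la, lb = labels
    raa = session_avg_corr(pred_a, obs_a)
    rab = session_avg_corr(pred_a, obs_b)
    rba = session_avg_corr(pred_b, obs_a)
    rbb = session_avg_corr(pred_b, obs_b)
    tied = (raa == rab) or (rba == rbb)
    assign_a = la if raa >= rab else lb
    assign_b = lb if rbb > rba else la
    assignment = {la: assign_a, lb: assign_b}
    correct = assign_a == la and assign_b == lb
    return assignment, correct, tied


def subject_accuracy(splits: list[SplitResult]) -> float:
    """Fraction of splits in which both predicted maps were correct."""
    if not splits:
        raise ValueError("no splits provided")
    return float(np.mean([s.correct for s in splits]))


def task_noise_ceiling(
    observed_sessions: np.ndarray, timepoints
) -> tuple[float, int, int]:
    """Noise ceiling for one (subject, task): sqrt of between-session map
    reliability, estimated within scanning timepoints.

    Every within-timepoint session pair yields one reliability r; non-positive
    r makes sqrt undefined and that estimate is excluded. Estimates from
    different timepoints are averaged.

    Returns ``(ceiling, n_valid, n_excluded)``; ceiling is NaN if no valid
    estimate remains.
    """
    obs = np.atleast_2d(np.asarray(observed_sessions, dtype=float))
    timepoints = np.asarray(list(timepoints))
    if obs.shape[0] < 2:
        raise ValueError("noise ceiling needs at least 2 sessions")
    if timepoints.shape[0] != obs.shape[0]:
        raise ValueError("one timepoint label per session required")
    estimates = []
    n_excluded = 0
    for tp in np.unique(timepoints):
        idx = np.flatnonzero(timepoints == tp)
        for i, j in combinations(idx, 2):
            r = pearson_r(obs[i], obs[j])
            if r <= 0:
                n_excluded += 1
            else:
                estimates.append(np.sqrt(r))
    ceiling = float(np.mean(estimates)) if estimates else float("nan")
    return ceiling, len(estimates), n_excluded


def noise_ceiling_table(dataset) -> pd.DataFrame:
    """Per-(subject, task) noise ceilings for a whole dataset.

    Excluded (non-positive reliability) estimates are counted per row and a
    summary warning is emitted when any occur.
    """
    rows = []
    total_excluded = 0
    for sub in dataset.subjects:
        for task in sub.task_ids:
            ceiling, n_valid, n_exc = task_noise_ceiling(
                sub.maps[task], sub.timepoints[task]
            )
            total_excluded += n_exc
            rows.append(
                {
                    "subject": sub.subject,
                    "task": task,
                    "ceiling": ceiling,
                    "n_estimates": n_valid,
                    "n_excluded": n_exc,
                }
            )
    if total_excluded:
        warnings.warn(
            f"{total_excluded} non-positive between-session reliabilities "
            "excluded from noise ceilings",
            stacklevel=2,
        )
    return pd.DataFrame(rows)


def aggregate_metrics(
    splits: list[SplitResult],
    noise_ceilings: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize split results per subject and per (subject, task).

    Per subject: classification accuracy plus the mean of the 2 x C(n,2)
    per-task session-averaged correlations and R^2 values. Per (subject,
    task): the mean correlation over the task's n-1 split appearances,
    joined with its noise ceiling when provided.
    """
    if not splits:
        raise ValueError("no splits provided")
    per_task_rows = []
    for s in splits:
        for task in s.tasks:
            per_task_rows.append(
                {
                    "subject": s.subject,
                    "task": task,
                    "r": s.r[task],
                    "r2": s.r2[task],
                    "correct": s.correct,
                }
            )
    long = pd.DataFrame(per_task_rows)

    per_subject = (
        long.groupby("subject")
        .agg(mean_r=("r", "mean"), mean_r2=("r2", "mean"))
        .reset_index()
    )
    acc = (
        pd.DataFrame(
            {"subject": [s.subject for s in splits],
             "correct": [s.correct for s in splits]}
        )
        .groupby("subject")["correct"]
        .mean()
        .rename("accuracy")
        .reset_index()
    )
    per_subject = acc.merge(per_subject, on="subject")

    per_task = (
        long.groupby(["subject", "task"])
        .agg(mean_r=("r", "mean"), mean_r2=("r2", "mean"),
             n_appearances=("r", "size"))
        .reset_index()
    )
    if noise_ceilings is not None:
        per_task = per_task.merge(
            noise_ceilings[["subject", "task", "ceiling"]],
            on=["subject", "task"],
            how="left",
        )
    return per_subject, per_task


@dataclass
class FeatureSetComparison:
    """Repeated-measures ANOVA over feature sets plus Bonferroni paired t-tests."""

    f_statistic: float
    df: tuple[int, int]
    p_value: float
    pairwise: pd.DataFrame = field(repr=False)


def compare_feature_sets(accuracies: pd.DataFrame) -> FeatureSetComparison:
    """Compare per-subject accuracies across feature sets.

    ``accuracies``: one row per subject, one column per feature set. A
    one-way repeated-measures ANOVA (F with df (k-1, (k-1)(n-1))) is followed
    by paired t-tests for every pair of columns with Bonferroni correction
    (p multiplied by the number of pairs, capped at 1). Zero-variance paired
    differences are flagged degenerate.
    """
    data = accuracies.to_numpy(dtype=float)
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValueError("need >= 2 subjects and >= 2 feature sets")
    grand = data.mean()
    ss_cond = n * float(np.sum((data.mean(axis=0) - grand) ** 2))
    ss_subj = k * float(np.sum((data.mean(axis=1) - grand) ** 2))
    ss_tot = float(np.sum((data - grand) ** 2))
    ss_err = max(ss_tot - ss_cond - ss_subj, 0.0)
    df1, df2 = k - 1, (k - 1) * (n - 1)
    # treat sums of squares at float-cancellation scale as exact zeros
    tiny = 1e-12 * max(ss_tot, 1.0)
    if ss_cond <= tiny:
        f_stat, p = 0.0, 1.0
    elif ss_err <= tiny:
        f_stat, p = float("inf"), 0.0
    else:
        f_stat = (ss_cond / df1) / (ss_err / df2)
        p = float(stats.f.sf(f_stat, df1, df2))

    pairs = list(combinations(accuracies.columns, 2))
    rows = []
    for a, b in pairs:
        diff = data[:, accuracies.columns.get_loc(a)] - data[
            :, accuracies.columns.get_loc(b)
        ]
        diff_scale = max(float(np.abs(diff).max()), 1.0)
        degenerate = bool(np.std(diff, ddof=1) <= 1e-10 * diff_scale)
        if degenerate:
            t = float("nan") if np.mean(diff) == 0 else float("inf") * np.sign(
                np.mean(diff)
            )
            p_raw = float("nan") if np.isnan(t) else 0.0
        else:
            t, p_raw = stats.ttest_rel(
                data[:, accuracies.columns.get_loc(a)],
                data[:, accuracies.columns.get_loc(b)],
            )
        rows.append(
            {
                "set_a": a,
                "set_b": b,
                "t": float(t),
                "df": n - 1,
                "p_bonferroni": (
                    float("nan") if np.isnan(p_raw)
                    else min(1.0, float(p_raw) * len(pairs))
                ),
                "degenerate": degenerate,
            }
        )
    return FeatureSetComparison(
        f_statistic=f_stat, df=(df1, df2), p_value=p, pairwise=pd.DataFrame(rows)
    )


def split_type_breakdown(
    splits: list[SplitResult],
    meta_task: dict[str, str],
    task_ids: list[str],
) -> pd.DataFrame:
    """Accuracy by number of held-out tasks (0, 1 or 2) whose meta-task also
    appears among the training tasks of that split."""
    unmapped = [t for t in task_ids if t not in meta_task]
    if unmapped:
        raise ValueError(f"tasks missing from meta-task mapping: {unmapped}")
    rows = []
    for s in splits:
        held = set(s.tasks)
        training_metas = {meta_task[t] for t in task_ids if t not in held}
        label = sum(1 for t in s.tasks if meta_task[t] in training_metas)
        rows.append({"label": label, "correct": s.correct})
    df = pd.DataFrame(rows)
    return (
        df.groupby("label")
        .agg(accuracy=("correct", "mean"), n_splits=("correct", "size"))
        .reset_index()
    )


def simulate_random_classifier(
    n_trials: int, n_regions: int = 50, rng=None
) -> float:
    """Empirical both-correct rate of the two-way classifier on structureless
    data (independent Gaussian maps); converges to the 25% chance level."""
    rng = np.random.default_rng(rng)
    correct = 0
    for _ in range(n_trials):
        pred_a, pred_b = rng.standard_normal((2, n_regions))
        obs_a = rng.standard_normal((2, n_regions))
        obs_b = rng.standard_normal((2, n_regions))
        _, ok, _ = two_way_classify(pred_a, pred_b, obs_a, obs_b)
        correct += ok
    return correct / n_trials
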