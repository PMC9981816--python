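"""Synthetic task-battery datasets with known ground truth.

Emulates the structure of a dense-sampling task-fMRI study — a battery of
task conditions annotated with ontological features, parcellated z-score
activation maps measured over two or four imaging sessions per task, and a
partition of regions into resting-state networks — while making the
generative model fully known:

    z[session, region] = f(task) . W[subject][:, region]
                         + mu[region] + N(0, noise_sd)

where ``W[subject]`` perturbs a group weight matrix with planted
network-signature structure (for each network, a few features have elevated
mean weight across that network's regions) and ``mu`` is a per-region mean
activation shared by all tasks.

Every downstream stage of the pipeline (encoding, evaluation, null model,
clustering, transfer, network profiles) can therefore be tested against
ground truth. All randomness flows through one explicitly passed
``numpy.random.Generator``; the same seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SyntheticConfig
from .datasets import ActivationDataset, SubjectData
from .features import (
    CLASS_COGNITIVE,
    CLASS_PERCEPTUAL_MOTOR,
    FeatureMatrix,
    recode_parametric,
)

# raw magnitude pools for parametric features, in the style of
# response-alternative counts and per-block response counts
PARAMETRIC_LEVEL_POOLS = (
    (0, 1, 2, 4, 6, 7),
    (0, 1, 2, 5, 7, 8, 12, 15),
    (0, 1, 2, 3, 4, 5, 7, 8, 12, 15),
)
PARAMETRIC_NAMES = ("response_alternatives", "left_hand_responses",
                    "right_hand_responses")

_MAX_MATRIX_REDRAWS = 100
_MAX_COLUMN_REDRAWS = 1000


@dataclass
class GroundTruth:
    """Generative parameters behind a synthetic dataset.

    ``signatures`` maps each network id to the indices of its planted
    signature features, which parameter-recovery and feature-importance
    checks compare against.
    """

    group_weights: np.ndarray          # (n_features, n_regions)
    subject_weights: list[np.ndarray]  # each (n_features, n_regions)
    network_labels: np.ndarray         # (n_regions,) ints in [0, n_networks)
    region_means: np.ndarray           # (n_regions,)
    noise_sd: float
    signatures: dict[int, np.ndarray]

    def __post_init__(self) -> None:
        k, r = self.group_weights.shape
        for w in self.subject_weights:
            if w.shape != (k, r):
                raise ValueError("subject weight shape inconsistent with group")
        if self.network_labels.shape != (r,):
            raise ValueError("every region needs exactly one network label")
        if self.region_means.shape != (r,):
            raise ValueError("region_means inconsistent with region count")


def _draw_binary_column(n_tasks: int, density: float, rng) -> np.ndarray:
    """Bernoulli column, redrawn until non-constant (constant columns carry
    no signal and make ridge weights unidentifiable)."""
    for _ in range(_MAX_COLUMN_REDRAWS):
        col = (rng.random(n_tasks) < density).astype(float)
        if 0 < col.sum() < n_tasks:
            return col
    raise RuntimeError("could not draw a non-constant binary column")


def _draw_parametric_column(n_tasks: int, pool, rng) -> np.ndarray:
    for _ in range(_MAX_COLUMN_REDRAWS):
        raw = rng.choice(np.asarray(pool, dtype=float), size=n_tasks)
        if np.unique(raw).size >= 2:
            return recode_parametric(raw)
    raise RuntimeError("could not draw a parametric column with >= 2 levels")


def generate_annotation_matrix(config: SyntheticConfig, rng) -> FeatureMatrix:
    """Draw a task-by-feature annotation matrix with pairwise-distinct rows.

    Binary features are Bernoulli(``binary_density``); the last
    ``n_parametric`` columns are parametric, drawn from small magnitude pools
    and recoded to dense ranks on [0, 1]. The first ``n_cognitive`` columns
    are classed Cognitive, the rest Perceptual-Motor.

    Raises
    ------
    ValueError
        If pairwise-distinct task rows cannot be produced within a bounded
        number of redraws (degenerate configuration).
    """
    t, k = config.n_tasks, config.n_features
    n_par = config.n_parametric
    for _ in range(_MAX_MATRIX_REDRAWS):
        values = np.empty((t, k))
        for j in range(k - n_par):
            values[:, j] = _draw_binary_column(t, config.binary_density, rng)
        for i in range(n_par):
            pool = PARAMETRIC_LEVEL_POOLS[i % len(PARAMETRIC_LEVEL_POOLS)]
            values[:, k - n_par + i] = _draw_parametric_column(t, pool, rng)
        if np.unique(values, axis=0).shape[0] == t:
            break
    else:
        raise ValueError(
            "could not generate pairwise-distinct task rows; configuration "
            "is degenerate (n_features too small for n_tasks?)"
        )

    feature_ids = []
    for j in range(k - n_par):
        prefix = "cog" if j < config.n_cognitive else "pm"
        feature_ids.append(f"{prefix}_{j:02d}")
    for i in range(n_par):
        name = (PARAMETRIC_NAMES[i] if i < len(PARAMETRIC_NAMES)
                else f"parametric_{i}")
        feature_ids.append(name)
    classes = np.array(
        [CLASS_COGNITIVE] * config.n_cognitive
        + [CLASS_PERCEPTUAL_MOTOR] * (k - config.n_cognitive),
        dtype=object,
    )
    parametric = np.zeros(k, dtype=bool)
    parametric[k - n_par:] = True if n_par else False
    return FeatureMatrix(
        task_ids=[f"task_{i:02d}" for i in range(t)],
        feature_ids=feature_ids,
        values=values,
        feature_class=classes,
        parametric=parametric,
    )


def generate_ground_truth(config: SyntheticConfig, rng) -> GroundTruth:
    """Draw network-structured group weights and per-subject perturbations.

    Network sizes are balanced to within one region. For each network,
    3-6 randomly chosen signature features receive a mean shift of
    ``signature_shift`` across that network's regions, on top of an
    unstructured N(0, baseline_weight_sd) background.
    """
    k, r = config.n_features, config.n_regions
    base, rem = divmod(r, config.n_networks)
    sizes = [base + (1 if i < rem else 0) for i in range(config.n_networks)]
    labels = rng.permutation(np.repeat(np.arange(config.n_networks), sizes))

    group = rng.normal(0.0, config.baseline_weight_sd, size=(k, r))
    signatures: dict[int, np.ndarray] = {}
    for net in range(config.n_networks):
        n_sig = min(int(rng.integers(3, 7)), k)
        feats = rng.choice(k, size=n_sig, replace=False)
        regions = np.flatnonzero(labels == net)
        group[np.ix_(feats, regions)] += config.signature_shift
        signatures[net] = np.sort(feats)

    region_means = rng.normal(0.0, config.mean_map_sd, size=r)
    subject_weights = [
        group + rng.normal(0.0, config.subject_weight_sd, size=(k, r))
        for _ in range(config.n_subjects)
    ]
    return GroundTruth(
        group_weights=group,
        subject_weights=subject_weights,
        network_labels=labels,
        region_means=region_means,
        noise_sd=config.noise_sd,
        signatures=signatures,
    )


def generate_activations(
    truth: GroundTruth,
    features: FeatureMatrix,
    config: SyntheticConfig,
    rng,
) -> ActivationDataset:
    """Simulate session-level activation maps for every subject.

    A seeded random subset of ``n_four_session_tasks`` tasks gets four
    sessions (timepoints 0,0,1,1 — two visits); the rest get two sessions at
    a single visit. Each session map is the task's feature vector times the
    subject's weights, plus the shared region means and i.i.d. Gaussian
    noise.
    """
    k, r = truth.group_weights.shape
    if features.n_features != k:
        raise ValueError(
            f"feature matrix has {features.n_features} features but ground "
            f"truth has {k}"
        )
    if features.n_tasks != config.n_tasks:
        raise ValueError("feature matrix task count inconsistent with config")
    if len(truth.subject_weights) != config.n_subjects:
        raise ValueError("ground truth subject count inconsistent with config")

    four_idx = set(
        rng.choice(config.n_tasks, size=config.n_four_session_tasks,
                   replace=False).tolist()
    )
    subjects = []
    for s, w in enumerate(truth.subject_weights):
        maps = {}
        timepoints = {}
        for i, task in enumerate(features.task_ids):
            n_sessions = 4 if i in four_idx else 2
            tps = (0, 0, 1, 1) if n_sessions == 4 else (0, 0)
            clean = features.values[i] @ w + truth.region_means
            noise = rng.normal(0.0, config.noise_sd, size=(n_sessions, r))
            maps[task] = clean[None, :] + noise
            timepoints[task] = tps
        subjects.append(
            SubjectData(
                subject=f"sub-{s:02d}",
                task_ids=list(features.task_ids),
                maps=maps,
                timepoints=timepoints,
            )
        )
    return ActivationDataset(subjects=subjects, task_ids=list(features.task_ids))


def generate_dataset(
    config: SyntheticConfig, seed: int | None = None
) -> tuple[FeatureMatrix, GroundTruth, ActivationDataset]:
    """Convenience wrapper: annotation matrix, ground truth and activations
    from a single seeded generator (``seed`` falls back to ``config.seed``)."""
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    fm = generate_annotation_matrix(config, rng)
    truth = generate_ground_truth(config, rng)
    data = generate_activations(truth, fm, config, rng)
    return fm, truth, data
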