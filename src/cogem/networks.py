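"""Resting-state-network profiles of encoding-model coefficients.

Regional model coefficients are aggregated into network-level feature
importances (subjects averaged first, then regions within each network),
network functional specialization is tested by comparing the similarity of
coefficient vectors for region pairs within versus between networks against
a label-permutation null, and word-cloud-ready relative importances are
exported (positive features only, size proportional to magnitude).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


def _validate_atlas(labels: np.ndarray, n_regions: int) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.shape != (n_regions,):
        raise ValueError(
            f"atlas labels {labels.shape} inconsistent with {n_regions} regions"
        )
    return labels


def network_importance(
    subject_weights: list[np.ndarray],
    atlas: np.ndarray,
    feature_ids: list[str],
) -> pd.DataFrame:
    """Network x feature mean coefficients, aggregated in two stages.

    Coefficients are first averaged across subjects per (feature, region),
    then averaged across the regions of each network. ``subject_weights``
    are (n_features, n_regions) matrices, one per subject.
    """
    if not subject_weights:
        raise ValueError("need at least one subject's weights")
    k, r = subject_weights[0].shape
    for w in subject_weights:
        if w.shape != (k, r):
            raise ValueError("inconsistent weight matrix shapes")
    labels = _validate_atlas(atlas, r)
    mean_w = np.mean(subject_weights, axis=0)  # subjects first
    rows = {}
    for net in pd.unique(labels):
        rows[net] = mean_w[:, labels == net].mean(axis=1)
    table = pd.DataFrame.from_dict(rows, orient="index", columns=feature_ids)
    if not np.isfinite(table.to_numpy()).all():
        raise ValueError("non-finite importance values")
    return table.sort_index()


def within_between_similarity(
    subject_mean_weights: np.ndarray,
    atlas: np.ndarray,
    n_perm: int = 100,
    rng=None,
) -> tuple[float, float, float]:
    """Within- vs between-network similarity of regional coefficient vectors.

    Pearson correlations are computed for every region pair's
    (subject-averaged) weight vectors; the observed statistic is the mean
    within-network correlation minus the mean between-network correlation.
    The null permutes region -> network labels ``n_perm`` times; the
    reported p-value includes the observed statistic in the denominator,
    p = (1 + #{perm >= obs}) / (1 + n_perm), so p >= 1/(n_perm + 1).

    Returns ``(within_mean, between_mean, p_value)``.
    """
    W = np.asarray(subject_mean_weights, dtype=float)
    k, r = W.shape
    labels = _validate_atlas(atlas, r)
    counts = pd.Series(labels).value_counts()
    if (counts < 2).any():
        raise ValueError("every network needs at least 2 regions")
    if counts.size < 2:
        raise ValueError("need at least 2 networks for a between mean")
    if k < 3:
        raise ValueError("need at least 3 features to correlate regions")
    corr = np.corrcoef(W.T)
    iu = np.triu_indices(r, k=1)
    pair_r = corr[iu]

    def stat(lab):
        same = lab[iu[0]] == lab[iu[1]]
        return pair_r[same].mean(), pair_r[~same].mean()

    within, between = stat(labels)
    observed = within - between
    rng = np.random.default_rng(rng)
    exceed = 0
    for _ in range(n_perm):
        w, b = stat(rng.permutation(labels))
        if (w - b) >= observed:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return float(within), float(between), float(p)


def wordcloud_weights(table: pd.DataFrame, network) -> pd.Series:
    """Relative word-cloud sizes for one network's features.

    Only strictly positive coefficients are kept; sizes are proportional to
    coefficient magnitude (scaled so the largest is 1), so a feature with
    twice the magnitude of another renders at twice the size.
    """
    if network not in table.index:
        raise ValueError(f"network {network!r} not in importance table")
    row = table.loc[network]
    positive = row[row > 0]
    if positive.empty:
        warnings.warn(
            f"network {network!r} has no positive feature weights",
            stacklevel=2,
        )
        return positive
    return positive / positive.max()
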