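"""Cognitive-space structure from classifier generalization errors.

Classification outcomes are pooled over subjects and splits into a task
confusion matrix, projected into feature space by multiplying with the
annotation matrix, converted into a feature representational dissimilarity
matrix (1 - Pearson r between feature profiles), and clustered with UPGMA
(average linkage) hierarchical agglomeration.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from .evaluation import SplitResult
from .features import FeatureMatrix


def build_confusion(
    splits: list[SplitResult], task_ids: list[str]
) -> np.ndarray:
    """Task confusion counts pooled over subjects and CV splits.

    ``counts[i, j]``: how often task i's predicted map was assigned to task
    j. Each split contributes two decisions, so the total count equals
    2 x n_splits, and each row sums to the row task's appearance count.
    """
    index = {t: i for i, t in enumerate(task_ids)}
    counts = np.zeros((len(task_ids), len(task_ids)), dtype=int)
    for s in splits:
        extra = set(s.tasks) - set(index)
        if extra:
            raise ValueError(f"split tasks not in task set: {sorted(extra)}")
        for true_task, assigned in s.assignment.items():
            counts[index[true_task], index[assigned]] += 1
    return counts


def project_to_cognitive(
    confusion: np.ndarray, fm: FeatureMatrix, normalize: bool = True
) -> np.ndarray:
    """Project the confusion matrix into feature space: ``conf @ features``.

    With ``normalize`` (default) confusion rows are first scaled to
    probabilities so each task contributes equally regardless of how many
    splits it appeared in.
    """
    conf = np.asarray(confusion, dtype=float)
    if conf.shape != (fm.n_tasks, fm.n_tasks):
        raise ValueError(
            f"confusion shape {conf.shape} does not match {fm.n_tasks} tasks"
        )
    if normalize:
        sums = conf.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValueError("confusion matrix has empty rows")
        conf = conf / sums
    return conf @ fm.values


def feature_rdm(projected: np.ndarray) -> np.ndarray:
    """Feature-by-feature dissimilarity: 1 - Pearson r between columns.

    Symmetric, zero diagonal, values in [0, 2]. Constant columns have
    undefined correlations; the affected pairs are set to NaN and reported
    via a warning.
    """
    proj = np.asarray(projected, dtype=float)
    if proj.shape[1] < 2:
        raise ValueError("need at least 2 feature columns")
    sd = proj.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(proj.T)
    rdm = 1.0 - corr
    rdm = (rdm + rdm.T) / 2.0  # remove float asymmetry from corrcoef
    np.fill_diagonal(rdm, 0.0)
    if constant.size:
        warnings.warn(
            f"{constant.size} constant feature columns give undefined "
            f"distances (set to NaN): indices {constant.tolist()}",
            stacklevel=2,
        )
        rdm[constant, :] = np.nan
        rdm[:, constant] = np.nan
        np.fill_diagonal(rdm, 0.0)
    return rdm


def upgma_cluster(rdm: np.ndarray) -> np.ndarray:
    """UPGMA (average-linkage) hierarchical clustering of an RDM.

    Returns the standard (n-1) x 4 linkage table; merge heights are
    arithmetic means of all between-cluster member-pair distances and are
    monotone non-decreasing. SciPy's deterministic tie handling (first
    minimal pair in condensed order) is relied on for reproducibility.
    """
    rdm = np.asarray(rdm, dtype=float)
    if np.isnan(rdm).any():
        raise ValueError("RDM contains NaN distances")
    if not np.allclose(rdm, rdm.T, atol=1e-10):
        raise ValueError("RDM must be symmetric")
    condensed = squareform((rdm + rdm.T) / 2.0, checks=False)
    return linkage(condensed, method="average")


def linkage_to_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Export a linkage table as a Newick string with branch lengths equal
    to the height difference between a node and its parent."""
    tree = to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{labels[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"
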