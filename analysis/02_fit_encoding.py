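"""Fit encoding models under leave-two-out CV for all three feature sets.

For every subject and each feature set (All, Cognitive, Perceptual-Motor):
nested-CV ridge fits, two-way classification, session-averaged map r and
R^2. Also computes noise ceilings, the model-vs-ceiling correlation and the
repeated-measures comparison of feature sets. Writes per-split detail,
per-subject summaries and the ceiling table under results/encoding/.

Usage: python analysis/02_fit_encoding.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cogem import (
    aggregate_metrics,
    compare_feature_sets,
    noise_ceiling_table,
    read_feature_tsv,
    run_subject_cv,
    subject_accuracy,
    subset_features,
)
from cogem.datasets import read_activations_tsv

INNER_K = 5


def splits_to_frame(splits):
    rows = []
    for s in splits:
        a, b = s.tasks
        rows.append(
            {
                "subject": s.subject, "task_a": a, "task_b": b,
                "alpha": s.alpha, "r_a": s.r[a], "r_b": s.r[b],
                "r2_a": s.r2[a], "r2_b": s.r2[b],
                "assigned_a": s.assignment[a], "assigned_b": s.assignment[b],
                "correct": s.correct, "tied": s.tied,
            }
        )
    return pd.DataFrame(rows)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/encoding"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fm = read_feature_tsv(args.data / "features.tsv")
    data = read_activations_tsv(args.data / "activations.tsv")
    ceilings = noise_ceiling_table(data)
    ceilings.to_csv(args.out / "noise_ceilings.tsv", sep="\t", index=False)

    accuracies = {}
    for subset_name in ("all", "cognitive", "perceptual_motor"):
        sub_fm = subset_features(fm, subset_name)
        all_splits = []
        for i, sub in enumerate(data.subjects):
            all_splits += run_subject_cv(
                sub, sub_fm, inner_k=INNER_K,
                rng=np.random.default_rng([args.seed, 2, i]),
            )
        detail = splits_to_frame(all_splits)
        detail.to_csv(args.out / f"splits_{subset_name}.tsv", sep="\t",
                      index=False)
        per_subject, per_task = aggregate_metrics(all_splits, ceilings)
        per_subject.to_csv(args.out / f"per_subject_{subset_name}.tsv",
                           sep="\t", index=False)
        per_task.to_csv(args.out / f"per_task_{subset_name}.tsv", sep="\t",
                        index=False)
        accuracies[subset_name] = (
            detail.groupby("subject")["correct"].mean().sort_index().to_numpy()
        )
        print(
            f"{subset_name:>17}: accuracy {accuracies[subset_name].mean():.3f}, "
            f"map r {per_subject['mean_r'].mean():.3f}, "
            f"R2 {per_subject['mean_r2'].mean():.3f}"
        )
        if subset_name == "all":
            valid = per_task.dropna(subset=["ceiling"])
            r = np.corrcoef(valid["mean_r"], valid["ceiling"])[0, 1]
            print(
                f"    noise ceiling mean {valid['ceiling'].mean():.3f}; "
                f"model-vs-ceiling r {r:.3f}"
            )

    comparison = compare_feature_sets(pd.DataFrame(accuracies))
    comparison.pairwise.to_csv(args.out / "feature_set_ttests.tsv", sep="\t",
                               index=False)
    print(
        f"feature sets differ: F({comparison.df[0]}, {comparison.df[1]}) = "
        f"{comparison.f_statistic:.2f}, p = {comparison.p_value:.2g}"
    )


if __name__ == "__main__":
    main()
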