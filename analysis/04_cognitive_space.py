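"""Cognitive-space structure from classifier generalization errors.

Rebuilds the task confusion matrix from the saved per-split classification
outcomes (All feature set), projects it into feature space, computes the
1-correlation feature RDM and clusters it with UPGMA. Writes the confusion
matrix, the RDM, the linkage table and the dendrogram as Newick.

Usage: python analysis/04_cognitive_space.py
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cogem import (
    build_confusion,
    feature_rdm,
    linkage_to_newick,
    project_to_cognitive,
    read_feature_tsv,
    upgma_cluster,
)
from cogem.evaluation import SplitResult


def frame_to_splits(df: pd.DataFrame) -> list[SplitResult]:
    splits = []
    for row in df.itertuples():
        splits.append(
            SplitResult(
                subject=row.subject, tasks=(row.task_a, row.task_b),
                alpha=row.alpha,
                r={row.task_a: row.r_a, row.task_b: row.r_b},
                r2={row.task_a: row.r2_a, row.task_b: row.r2_b},
                assignment={row.task_a: row.assigned_a,
                            row.task_b: row.assigned_b},
                correct=bool(row.correct), tied=bool(row.tied),
            )
        )
    return splits


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--encoding", type=Path,
                        default=Path("results/encoding"))
    parser.add_argument("--out", type=Path, default=Path("results/structure"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fm = read_feature_tsv(args.data / "features.tsv")
    detail = pd.read_csv(args.encoding / "splits_all.tsv", sep="\t")
    splits = frame_to_splits(detail)

    conf = build_confusion(splits, fm.task_ids)
    pd.DataFrame(conf, index=fm.task_ids, columns=fm.task_ids).to_csv(
        args.out / "confusion.tsv", sep="\t"
    )
    n_subjects = detail["subject"].nunique()
    assert conf.sum() == 2 * len(splits)
    diag_rate = np.diag(conf).sum() / conf.sum()
    print(
        f"confusion over {len(splits)} splits from {n_subjects} subjects; "
        f"{diag_rate:.1%} of decisions on the diagonal"
    )

    projected = project_to_cognitive(conf, fm)
    rdm = feature_rdm(projected)
    pd.DataFrame(rdm, index=fm.feature_ids, columns=fm.feature_ids).to_csv(
        args.out / "feature_rdm.tsv", sep="\t"
    )
    Z = upgma_cluster(rdm)
    pd.DataFrame(Z, columns=["left", "right", "height", "size"]).to_csv(
        args.out / "linkage.tsv", sep="\t", index=False
    )
    newick = linkage_to_newick(Z, fm.feature_ids)
    (args.out / "dendrogram.nwk").write_text(newick + "\n")
    print(
        f"UPGMA tree over {fm.n_features} features; first merge at height "
        f"{Z[0, 2]:.3f}, last at {Z[-1, 2]:.3f}; outputs in {args.out}"
    )


if __name__ == "__main__":
    main()
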