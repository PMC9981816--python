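"""Between-subject generalization of encoding models.

Trains each subject's models on all of their tasks, then evaluates two-way
classification of every task pair on every other subject (and on the source
subject itself). Writes the source x target accuracy and correlation
matrices.

Usage: python analysis/05_subject_transfer.py [--seed 1]
"""

import argparse
from pathlib import Path

import numpy as np

from cogem import fit_full, read_feature_tsv, transfer_evaluate
from cogem.datasets import read_activations_tsv

INNER_K = 5


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--data", type=Path, default=Path("results/data"))
    parser.add_argument("--out", type=Path, default=Path("results/transfer"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fm = read_feature_tsv(args.data / "features.tsv")
    data = read_activations_tsv(args.data / "activations.tsv")

    fits = {
        s.subject: fit_full(
            s, fm, inner_k=INNER_K,
            rng=np.random.default_rng([args.seed, 3, i]),
        )
        for i, s in enumerate(data.subjects)
    }
    res = transfer_evaluate(fits, data, fm)
    res.accuracy.to_csv(args.out / "transfer_accuracy.tsv", sep="\t")
    res.correlation.to_csv(args.out / "transfer_correlation.tsv", sep="\t")

    print(
        f"self-transfer accuracy M = {res.self_transfer.mean():.3f}; "
        f"cross-subject M = {res.cross_transfer_mean:.3f} "
        f"(chance 0.25)"
    )
    corr = res.correlation.to_numpy()
    off = ~np.eye(corr.shape[0], dtype=bool)
    print(
        f"self map r M = {np.diag(corr).mean():.3f}; "
        f"cross map r M = {corr[off].mean():.3f}; matrices in {args.out}"
    )


if __name__ == "__main__":
    main()
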