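"""Generate the synthetic task battery the downstream analyses run on.

Writes the annotation matrix, session-level activations, network atlas,
ground-truth group weights and the generator configuration under
results/data/. All later scripts read these files, so the whole analysis is
reproducible from this step alone.

Usage: python analysis/01_simulate.py [--seed 1] [--out results/data]
"""

import argparse
from pathlib import Path

import pandas as pd

from cogem import SyntheticConfig, generate_dataset, write_feature_tsv
from cogem.datasets import write_activations_tsv, write_network_labels

# Desk-scale conditions: the full design's structure (7 networks, 2-or-4
# sessions, 3 parametric features, Cognitive:PM ratio 2:1) with counts
# reduced for fast nested cross-validation.
CONFIG = SyntheticConfig(
    n_tasks=14, n_features=12, n_cognitive=8, n_parametric=3,
    n_regions=154, n_networks=7, n_subjects=3, n_four_session_tasks=5,
)


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--out", type=Path, default=Path("results/data"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    fm, truth, data = generate_dataset(CONFIG, seed=args.seed)

    write_feature_tsv(fm, args.out / "features.tsv")
    write_activations_tsv(data, args.out / "activations.tsv")
    write_network_labels(truth.network_labels, args.out / "atlas.tsv")
    pd.DataFrame(
        truth.group_weights, index=fm.feature_ids
    ).to_csv(args.out / "group_weights.tsv", sep="\t")
    pd.DataFrame(
        {str(net): pd.Series(feats) for net, feats in truth.signatures.items()}
    ).to_csv(args.out / "signatures.tsv", sep="\t", index=False)
    CONFIG.__class__(**{**CONFIG.__dict__, "seed": args.seed}).to_json(
        args.out / "config.json"
    )

    n_rows = sum(data.subjects[0].session_counts.values())
    print(
        f"simulated {CONFIG.n_tasks} tasks x {CONFIG.n_features} features "
        f"({CONFIG.n_cognitive} Cognitive), {CONFIG.n_subjects} subjects, "
        f"{CONFIG.n_regions} regions in {CONFIG.n_networks} networks"
    )
    print(f"{n_rows} session maps per subject; files in {args.out}")


if __name__ == "__main__":
    main()
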