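"""Configuration for the synthetic dataset generator.

The defaults mirror the structure of a dense-sampling task battery as used
for encoding-model analyses: 44 task conditions annotated with 36 ontological
features (24 Cognitive, 12 Perceptual-Motor, 3 of them parametric),
activation z-scores over 1000 cortical parcels for 23 analyzed subjects, with
14 tasks measured in four imaging sessions and the remainder in two.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic dataset generator.

    Noise and weight scales are in z-score / weight units:

    - ``noise_sd``: sd of additive Gaussian session noise per region.
    - ``subject_weight_sd``: sd of each subject's perturbation around the
      group-level encoding weights (individual variability).
    - ``baseline_weight_sd``: sd of the unstructured background weights.
    - ``signature_shift``: mean shift added to a network's signature
      features across that network's regions (the planted structure).
    - ``mean_map_sd``: sd of a per-region mean activation shared by all
      tasks; this shared component is what drives a task-shuffled null
      model's predictions toward the training mean.
    """

    n_tasks: int = 44
    n_features: int = 36
    n_cognitive: int = 24
    n_parametric: int = 3
    n_regions: int = 1000
    n_networks: int = 7
    n_subjects: int = 23
    n_four_session_tasks: int = 14
    noise_sd: float = 1.0
    subject_weight_sd: float = 0.1
    baseline_weight_sd: float = 0.1
    signature_shift: float = 1.0
    mean_map_sd: float = 1.0
    binary_density: float = 0.25
    seed: int | None = None

    def __post_init__(self) -> None:
        counts = {
            "n_tasks": self.n_tasks,
            "n_features": self.n_features,
            "n_regions": self.n_regions,
            "n_networks": self.n_networks,
            "n_subjects": self.n_subjects,
        }
        for name, value in counts.items():
            if int(value) != value or value < 1:
                raise ValueError(f"{name} must be an integer >= 1, got {value}")
        if not 0 <= self.n_parametric <= self.n_features:
            raise ValueError("n_parametric must lie in [0, n_features]")
        if not self.n_cognitive < self.n_features:
            raise ValueError("n_cognitive must be smaller than n_features")
        if self.n_cognitive < 0:
            raise ValueError("n_cognitive must be non-negative")
        if not 0 <= self.n_four_session_tasks <= self.n_tasks:
            raise ValueError("n_four_session_tasks must lie in [0, n_tasks]")
        for name in ("noise_sd", "subject_weight_sd", "baseline_weight_sd",
                     "mean_map_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.binary_density < 1:
            raise ValueError("binary_density must lie in (0, 1)")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            return cls(**json.load(fh))
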