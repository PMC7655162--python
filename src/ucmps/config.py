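"""Pipeline configuration: thresholds, model hyperparameters and the seed.

The defaults are the published ones where the study states them (fold-change
and significance cutoffs, the forest importance thresholds, 30-gene panel,
500 trees) and conventional values elsewhere.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["AnnSpec", "PipelineConfig"]


@dataclass
class AnnSpec:
    """Hyperparameters of the gene-weight network.

    One ReLU hidden layer feeding a 2-unit softmax; trained with Adam on
    categorical cross-entropy.
    """

    hidden_units: int = 8
    epochs: int = 200
    batch_size: int = 16
    learning_rate: float = 1e-3
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("hidden_units", "epochs", "batch_size"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")


@dataclass
class PipelineConfig:
    """End-to-end settings for the mPS pipeline.

    ``log2fc_threshold`` and ``alpha`` gate the DEG screen (strict
    inequalities); ``panel_size`` is the top-k forest selection;
    ``mda_threshold``/``mdg_threshold`` are the alternative absolute-cutoff
    selection mode (MDA on the scaled, divided-by-standard-error
    convention).  ``transfer_mode`` chooses how an external cohort is
    evaluated: ``retrain`` re-learns gene weights on that cohort,
    ``transfer`` applies the training-cohort weights unchanged.
    """

    log2fc_threshold: float = 2.0
    alpha: float = 0.05
    pseudocount: float = 1.0
    panel_size: int = 30
    mda_threshold: float = 3.56
    mdg_threshold: float = 0.53
    rf_trees: int = 500
    ann: AnnSpec = field(default_factory=AnnSpec)
    rng_seed: int = 0
    transfer_mode: str = "retrain"
    scale: str = "tpm_like"

    def __post_init__(self) -> None:
        if isinstance(self.ann, dict):
            self.ann = AnnSpec(**self.ann)
        if self.log2fc_threshold <= 0:
            raise ValueError("log2fc_threshold must be positive")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.pseudocount < 0:
            raise ValueError("pseudocount must be non-negative")
        if self.panel_size < 1:
            raise ValueError("panel_size must be >= 1")
        if self.rf_trees < 1:
            raise ValueError("rf_trees must be >= 1")
        if self.transfer_mode not in ("retrain", "transfer"):
            raise ValueError("transfer_mode must be 'retrain' or 'transfer'")
        if self.scale not in ("tpm_like", "log_intensity"):
            raise ValueError("scale must be 'tpm_like' or 'log_intensity'")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)
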