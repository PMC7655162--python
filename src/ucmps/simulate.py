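"""Synthetic two-group expression data with planted differential genes.

The generative model is Gaussian on the log2 scale: gene *g* in sample *s*
has log2 expression ``mu_g + delta_g * label(s) + eps`` with
``mu_g ~ Normal(baseline_log2_mean, gene_sd_log2)`` and
``eps ~ Normal(0, noise_sd_log2)``.  ``delta_g`` is ``+effect_log2`` for
planted up-regulated genes, ``-effect_log2`` for down-regulated genes and 0
for the null background.  On the ``tpm_like`` scale the log2 values are
exponentiated (minus a pseudocount, floored at zero) to give non-negative
linear abundances; ``log_intensity`` keeps the log2 values as-is, mimicking
processed microarray data.

Default group sizes mirror a strongly imbalanced training cohort (about
10:1 cases to controls), which is the regime where PR-AUC and ROC-AUC
diverge most.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix
from .scoring import GenePanel

__all__ = ["SimulationDesign", "simulate", "make_probe_level"]


@dataclass
class SimulationDesign:
    n_cases: int = 200
    n_controls: int = 20
    n_null_genes: int = 850
    n_up: int = 30
    n_down: int = 20
    effect_log2: float = 3.0
    baseline_log2_mean: float = 6.0
    gene_sd_log2: float = 1.5
    noise_sd_log2: float = 1.0
    scale: str = "tpm_like"
    pseudocount: float = 1.0
    duplicate_probe_fraction: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_cases, self.n_controls) < 2:
            raise ValueError("need at least 2 samples per group")
        if min(self.n_null_genes, self.n_up, self.n_down) < 0:
            raise ValueError("gene counts must be non-negative")
        if self.n_null_genes + self.n_up + self.n_down < 1:
            raise ValueError("design has no genes")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 is a magnitude; must be >= 0")
        if not 0 <= self.duplicate_probe_fraction <= 1:
            raise ValueError("duplicate_probe_fraction must lie in [0, 1]")
        if self.scale not in ("tpm_like", "log_intensity"):
            raise ValueError("scale must be 'tpm_like' or 'log_intensity'")

    @property
    def n_genes(self) -> int:
        return self.n_null_genes + self.n_up + self.n_down

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


def simulate(design: SimulationDesign) -> tuple[ExpressionMatrix, GenePanel]:
    """Draw one cohort from the design; returns the matrix and planted truth.

    Gene order is up genes, then down genes, then nulls; the truth panel
    lists only the planted genes with their directions.  Fixed seed gives a
    bit-identical matrix.
    """
    rng = np.random.default_rng(design.rng_seed)
    g, n = design.n_genes, design.n_samples

    labels = np.concatenate(
        [np.ones(design.n_cases, dtype=int), np.zeros(design.n_controls, dtype=int)]
    )
    delta = np.concatenate(
        [
            np.full(design.n_up, design.effect_log2),
            np.full(design.n_down, -design.effect_log2),
            np.zeros(design.n_null_genes),
        ]
    )
    mu = rng.normal(design.baseline_log2_mean, design.gene_sd_log2, size=g)
    log2_vals = (
        mu[:, None]
        + delta[:, None] * labels[None, :]
        + rng.normal(0.0, design.noise_sd_log2, size=(g, n))
    )
    if design.scale == "tpm_like":
        vals = np.maximum(np.exp2(log2_vals) - design.pseudocount, 0.0)
    else:
        vals = log2_vals

    gene_ids = (
        [f"UP{i:04d}" for i in range(design.n_up)]
        + [f"DN{i:04d}" for i in range(design.n_down)]
        + [f"NULL{i:04d}" for i in range(design.n_null_genes)]
    )
    sample_ids = [f"S{i:04d}" for i in range(n)]
    mat = ExpressionMatrix(
        pd.DataFrame(vals, index=gene_ids, columns=sample_ids),
        pd.Series(labels, index=sample_ids),
        scale=design.scale,
    )
    truth = GenePanel(
        [(gid, "up") for gid in gene_ids[: design.n_up]]
        + [(gid, "down") for gid in gene_ids[design.n_up : design.n_up + design.n_down]]
    )
    return mat, truth


def make_probe_level(
    mat: ExpressionMatrix,
    duplicate_probe_fraction: float,
    jitter_sd: float = 0.0,
    rng_seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Split a fraction of genes into 2-3 jittered probes.

    Returns a probe-level matrix and the probe-to-gene map, an exercise
    fixture for the median probe-collapse rule.  With fraction 0 the output
    is the input with an identity map; with jitter 0, collapsing the output
    recovers the input exactly (the median of identical copies).
    """
    if not 0 <= duplicate_probe_fraction <= 1:
        raise ValueError("duplicate_probe_fraction must lie in [0, 1]")
    rng = np.random.default_rng(rng_seed)
    n_dup = int(round(duplicate_probe_fraction * len(mat.gene_ids)))
    dup_genes = set(
        rng.choice(mat.gene_ids, size=n_dup, replace=False) if n_dup else []
    )

    rows, probe_ids, probe_map = [], [], {}
    for gid in mat.gene_ids:
        base = mat.values.loc[gid].to_numpy()
        n_probes = int(rng.integers(2, 4)) if gid in dup_genes else 1
        for k in range(n_probes):
            pid = f"{gid}_p{k}" if n_probes > 1 else gid
            jitter = rng.normal(0.0, jitter_sd, size=base.shape) if jitter_sd else 0.0
            rows.append(base + jitter)
            probe_ids.append(pid)
            probe_map[pid] = gid
    probe_mat = ExpressionMatrix(
        pd.DataFrame(np.asarray(rows), index=probe_ids, columns=mat.sample_ids),
        mat.labels,
        scale=mat.scale,
    )
    return probe_mat, probe_map
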