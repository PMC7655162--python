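import numpy as np
import pandas as pd
import pytest

from ucmps import ExpressionMatrix, GenePanel, PipelineConfig
from ucmps.simulate import SimulationDesign, simulate


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, hand-enumerable values."""
    values = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [10.0, 10.0, 2.0, 2.0], [5.0, 5.0, 5.0, 5.0]],
        index=["gA", "gB", "gC"],
        columns=["s1", "s2", "s3", "s4"],
    )
    labels = pd.Series([1, 1, 0, 0], index=values.columns)
    return ExpressionMatrix(values, labels)


@pytest.fixture
def default_config() -> PipelineConfig:
    return PipelineConfig(rng_seed=0)


@pytest.fixture
def signal_cohort():
    """Balanced cohort with strong planted signal (screen-recovery regime)."""
    design = SimulationDesign(
        n_cases=30,
        n_controls=30,
        n_null_genes=850,
        n_up=30,
        n_down=20,
        effect_log2=4.0,
        rng_seed=11,
    )
    return simulate(design)


def brute_roc_auc(predicted, labels) -> float:
    """Exhaustive pairwise Mann-Whitney oracle."""
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = predicted[labels == 1]
    controls = predicted[labels == 0]
    total = 0.0
    for c in cases:
        for k in controls:
            if c > k:
                total += 1.0
            elif c == k:
                total += 0.5
    return total / (len(cases) * len(controls))


def brute_pr_auc(predicted, labels) -> float:
    """Threshold-enumeration average-precision oracle (tied scores grouped)."""
    predicted = np.asarray(predicted, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = labels.sum()
    thresholds = sorted(set(predicted), reverse=True)
    area, prev_recall = 0.0, 0.0
    for t in thresholds:
        kept = predicted >= t
        tp = int(labels[kept].sum())
        precision = tp / int(kept.sum())
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def brute_bh(p_values) -> np.ndarray:
    """Literal step-up: adj for rank i = min over ranks j >= i of p_(j)*n/j."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.empty(n)
    for i in range(n):
        tail = [p[order[j]] * n / (j + 1) for j in range(i, n)]
        adj_sorted[i] = min(1.0, min(tail))
    out = np.empty(n)
    out[order] = adj_sorted
    return out
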