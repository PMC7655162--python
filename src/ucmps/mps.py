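"""Molecular prognostic score (mPS) and ranking metrics.

``mPS(sample) = sum_g Gene_Score(sample, g) * Gene_Weight(g)`` over the
panel genes.  The score is evaluated purely as a ranking of samples:

* **ROC-AUC** is computed as the Mann-Whitney pairwise statistic — the
  fraction of (case, control) pairs ranked correctly, ties counting one
  half — via midranks, which is exact under ties.
* **PR-AUC** uses the average-precision step convention
  ``sum_k (recall_k - recall_{k-1}) * precision_k`` over distinct score
  thresholds (tied scores form one threshold group); no interpolation is
  applied, because linearly interpolated precision-recall curves are
  optimistic.

Cases (label 1) are the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .ann import WeightedPanel
from .scoring import ScoreMatrix

__all__ = ["MpsResult", "compute_mps", "roc_auc", "pr_auc", "evaluate_mps"]


@dataclass
class MpsResult:
    """Per-sample mPS values plus attached ranking metrics."""

    mps: pd.Series
    labels: pd.Series
    roc_auc: float
    pr_auc: float
    panel_size: int

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mps.index)

    @property
    def n_cases(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mps": self.mps, "label": self.labels}
        ).rename_axis("sample_id")

    def metrics(self) -> dict:
        return {
            "roc_auc": self.roc_auc,
            "pr_auc": self.pr_auc,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "panel_size": self.panel_size,
        }


def compute_mps(scores: ScoreMatrix, weighted: WeightedPanel) -> pd.Series:
    """Weighted sum of Gene_Scores per sample.

    Score columns and weights are aligned by gene id; the gene sets must
    match exactly.
    """
    w = weighted.as_series()
    score_genes = set(scores.scores.columns)
    if score_genes != set(w.index):
        missing = score_genes ^ set(w.index)
        raise KeyError(f"score/weight gene sets differ: {sorted(missing)[:5]}")
    vals = scores.scores.loc[:, w.index].to_numpy() @ w.to_numpy()
    return pd.Series(vals, index=scores.scores.index, name="mps")


def _check_binary(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels, dtype=int)
    if not set(np.unique(labels)) <= {0, 1}:
        raise ValueError("labels must be binary 0/1")
    return labels


def roc_auc(predicted, labels) -> float:
    """Probability that a random case outranks a random control (ties half)."""
    predicted = np.asarray(predicted, dtype=float)
    labels = _check_binary(labels)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC-AUC needs both classes")
    ranks = rankdata(predicted)  # midranks
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def pr_auc(predicted, labels) -> float:
    """Average precision over distinct-score threshold groups."""
    predicted = np.asarray(predicted, dtype=float)
    labels = _check_binary(labels)
    n_pos = int(labels.sum())
    if n_pos == 0:
        raise ValueError("PR-AUC needs at least one case")
    order = np.argsort(-predicted, kind="stable")
    y = labels[order]
    s = predicted[order]
    # ends of tied-score groups
    group_end = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    tp = np.cumsum(y)[group_end]
    n_seen = group_end + 1
    precision = tp / n_seen
    recall = tp / n_pos
    return float(np.sum(np.diff(np.r_[0.0, recall]) * precision))


def evaluate_mps(
    mps: pd.Series, labels: pd.Series, panel_size: int | None = None
) -> MpsResult:
    """Bundle mPS values with ROC-AUC and PR-AUC."""
    labels = pd.Series(labels).reindex(mps.index)
    if labels.isna().any():
        raise ValueError("every sample with an mPS needs a label")
    return MpsResult(
        mps=mps,
        labels=labels.astype(int),
        roc_auc=roc_auc(mps.to_numpy(), labels.to_numpy()),
        pr_auc=pr_auc(mps.to_numpy(), labels.to_numpy()),
        panel_size=panel_size if panel_size is not None else -1,
    )
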