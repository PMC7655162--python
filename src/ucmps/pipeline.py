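"""End-to-end orchestration: screen -> select -> score -> weight -> mPS.

``run_pipeline`` executes every stage on one cohort and returns all
intermediate artifacts; ``validate_external`` applies a training-derived
panel to a second cohort, either re-learning gene weights on that cohort
(``retrain`` — the published protocol, which leaks the evaluation labels
into the weights and therefore flatters the metrics) or applying the frozen
training weights (``transfer`` — the leakage-free alternative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import pandas as pd

from .ann import AnnSpec, WeightedPanel, extract_gene_weights, train_ann
from .config import PipelineConfig
from .degs import DegRecord, screen_degs
from .forest import ImportanceRecord, rf_importance, select_panel
from .io_core import ExpressionMatrix
from .mps import MpsResult, compute_mps, evaluate_mps
from .scoring import GenePanel, ScoreMatrix, binarize, intersect_panel

logger = logging.getLogger("ucmps")

__all__ = ["PipelineResult", "run_pipeline", "validate_external"]


@dataclass
class PipelineResult:
    deg_table: list[DegRecord]
    importances: list[ImportanceRecord]
    panel: GenePanel
    scores: ScoreMatrix
    weighted: WeightedPanel
    result: MpsResult


def _seed(base: int, offset: int) -> int:
    return int((base * 1_000_003 + offset) % (2**31 - 1))


def run_pipeline(
    mat: ExpressionMatrix,
    config: PipelineConfig,
    selection_mode: str = "top_k",
) -> PipelineResult:
    """Run all stages on one labeled cohort."""
    mat.require_both_classes()
    deg_table = screen_degs(mat, config)
    deg_ids = [r.gene_id for r in deg_table if r.direction != "none"]
    if len(deg_ids) < 2:
        raise ValueError(f"only {len(deg_ids)} DEG(s) passed the screen")
    deg_mat = ExpressionMatrix(
        mat.values.loc[deg_ids], mat.labels, scale=mat.scale
    )
    importances = rf_importance(
        deg_mat, n_trees=config.rf_trees, rng_seed=_seed(config.rng_seed, 1)
    )
    panel = select_panel(importances, deg_table, config, mode=selection_mode)
    scores = binarize(mat, panel)
    ann_spec = replace(config.ann, rng_seed=_seed(config.rng_seed, 2))
    net = train_ann(scores, ann_spec)
    weighted = extract_gene_weights(net, panel)
    mps = compute_mps(scores, weighted)
    result = evaluate_mps(mps, scores.labels, panel_size=len(panel))
    logger.info(
        "training cohort: ROC-AUC %.4f, PR-AUC %.4f", result.roc_auc, result.pr_auc
    )
    return PipelineResult(deg_table, importances, panel, scores, weighted, result)


def validate_external(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    panel: GenePanel,
    spec: AnnSpec,
    mode: str = "retrain",
    train_weights: WeightedPanel | None = None,
) -> MpsResult:
    """Evaluate a training-derived panel on an independent cohort.

    The panel is intersected with the test cohort's genes and the test
    cohort is re-binarized against its own medians.  ``retrain`` learns new
    weights from the test cohort's scores; ``transfer`` applies
    ``train_weights`` (computed from the training cohort if not supplied),
    restricted to the intersected panel.
    """
    test.require_both_classes()
    sub_panel = intersect_panel(panel, test.gene_ids)
    test_scores = binarize(test, sub_panel)

    if mode == "retrain":
        logger.warning(
            "retrain mode re-learns weights on the evaluation cohort; the "
            "evaluation labels leak into the weights and the reported AUCs "
            "are optimistic"
        )
        net = train_ann(test_scores, spec)
        weighted = extract_gene_weights(net, sub_panel)
    elif mode == "transfer":
        if train_weights is None:
            train_scores = binarize(train, panel)
            net = train_ann(train_scores, spec)
            train_weights = extract_gene_weights(net, panel)
        w = train_weights.as_series().loc[sub_panel.gene_ids]
        weighted = WeightedPanel(sub_panel, w.to_numpy())
    else:
        raise ValueError("mode must be 'retrain' or 'transfer'")

    mps = compute_mps(test_scores, weighted)
    result = evaluate_mps(mps, test_scores.labels, panel_size=len(sub_panel))
    logger.info(
        "external cohort (%s): %d genes, ROC-AUC %.4f, PR-AUC %.4f",
        mode,
        len(sub_panel),
        result.roc_auc,
        result.pr_auc,
    )
    return result
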