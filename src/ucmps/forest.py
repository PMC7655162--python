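"""Random-forest variable importance and diagnostic-panel selection.

The forest is a bagged ensemble of CART classification trees (scikit-learn
``DecisionTreeClassifier`` grown on bootstrap resamples, sqrt-of-features
candidate splits).  Two importances are reported per gene, on the
conventions of the classical randomForest implementation:

* **MDA** (mean decrease in accuracy): for each tree, the drop in
  out-of-bag accuracy after permuting the gene's values among that tree's
  out-of-bag samples; the per-tree drops are averaged and divided by their
  standard error over trees (the "scaled" display convention, which is the
  scale on which absolute thresholds like 3.56 are meaningful).
* **MDG** (mean decrease in Gini): the total Gini-impurity decrease at
  nodes splitting on the gene, weighted by node sample counts, averaged
  over trees.

Panel selection defaults to the top-k genes by MDA (ties broken by MDG,
then gene id); an absolute-threshold mode (MDA >= t1 and MDG > t2) is also
provided because published cutoffs of that form are dataset-specific.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

from .config import PipelineConfig
from .degs import DegRecord
from .io_core import ExpressionMatrix
from .scoring import GenePanel

logger = logging.getLogger("ucmps")

__all__ = ["ImportanceRecord", "rf_importance", "select_panel", "importance_frame"]


@dataclass(frozen=True)
class ImportanceRecord:
    gene_id: str
    mda: float          # permutation importance scaled by its standard error
    mda_raw: float      # unscaled mean accuracy decrease
    mdg: float          # mean decrease in Gini (sample-count scale)
    rank_mda: int
    selected: bool = False


def _gini_decrease(tree, n_features: int) -> np.ndarray:
    """Per-feature total impurity decrease of one fitted tree (count scale)."""
    t = tree.tree_
    out = np.zeros(n_features)
    internal = t.children_left != -1
    idx = np.nonzero(internal)[0]
    w = t.weighted_n_node_samples
    dec = (
        w[idx] * t.impurity[idx]
        - w[t.children_left[idx]] * t.impurity[t.children_left[idx]]
        - w[t.children_right[idx]] * t.impurity[t.children_right[idx]]
    )
    np.add.at(out, t.feature[idx], dec)
    return out


def rf_importance(
    mat: ExpressionMatrix,
    n_trees: int = 500,
    rng_seed: int = 0,
    max_features: str | int = "sqrt",
) -> list[ImportanceRecord]:
    """Fit the forest and compute per-gene MDA and MDG importances.

    Deterministic for a fixed seed.  ``mat`` is typically restricted to the
    screened DEGs before calling.
    """
    mat.require_both_classes()
    if len(mat.gene_ids) < 2:
        raise ValueError("need at least two genes")
    X = np.ascontiguousarray(mat.values.to_numpy().T, dtype=np.float32)
    y = mat.labels.to_numpy()
    n, p = X.shape
    rng = np.random.default_rng(rng_seed)

    mdg_sum = np.zeros(p)
    deltas = np.zeros((n_trees, p))   # per-tree accuracy drops
    oob_trees = 0
    sample_idx = np.arange(n)
    for _ in range(n_trees):
        boot = rng.integers(0, n, size=n)
        oob = sample_idx[~np.isin(sample_idx, boot)]
        clf = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        clf.fit(X[boot], y[boot])
        mdg_sum += _gini_decrease(clf, p)
        if oob.size == 0:
            continue
        oob_trees += 1
        Xo = X[oob]
        yo = y[oob]
        classes = clf.classes_

        def _tree_predict(a: np.ndarray) -> np.ndarray:
            votes = np.asarray(clf.tree_.predict(a))
            return classes[votes.reshape(len(a), -1).argmax(1)]

        base_acc = (_tree_predict(Xo) == yo).mean()
        # one stacked prediction per tree: block f holds Xo with feature f permuted
        stacked = np.broadcast_to(Xo, (p, oob.size, p)).copy()
        rows = np.arange(oob.size)
        for f in range(p):
            stacked[f, rows, f] = Xo[rng.permutation(oob.size), f]
        flat = stacked.reshape(p * oob.size, p)
        pred = _tree_predict(flat)
        perm_acc = (pred.reshape(p, oob.size) == yo[None, :]).mean(axis=1)
        deltas[oob_trees - 1] = base_acc - perm_acc

    if oob_trees == 0:
        raise RuntimeError("no tree had out-of-bag samples; increase n_trees")
    d = deltas[:oob_trees]
    mda_raw = d.mean(axis=0)
    sd = d.std(axis=0)            # population SD over trees
    se = sd / np.sqrt(oob_trees)
    with np.errstate(divide="ignore", invalid="ignore"):
        mda = np.where(se > 0, mda_raw / se, 0.0)
    mdg = mdg_sum / n_trees

    # rank 1 = largest MDA; ties broken by MDG then gene id for determinism
    order = sorted(
        range(p), key=lambda i: (-mda[i], -mdg[i], mat.gene_ids[i])
    )
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return [
        ImportanceRecord(g, float(mda[i]), float(mda_raw[i]), float(mdg[i]), int(rank[i]))
        for i, g in enumerate(mat.gene_ids)
    ]


def select_panel(
    importances: list[ImportanceRecord],
    deg_table: list[DegRecord],
    config: PipelineConfig,
    mode: str = "top_k",
) -> GenePanel:
    """Choose the diagnostic panel from ranked importances.

    ``top_k`` keeps the ``config.panel_size`` highest-MDA genes (ties by
    MDG, then id); ``threshold`` keeps genes with
    ``mda >= config.mda_threshold`` and ``mdg > config.mdg_threshold``.
    Each selected gene carries its screened direction; genes whose screen
    direction is ``none`` cannot enter a panel.
    """
    direction = {r.gene_id: r.direction for r in deg_table}
    ranked = sorted(importances, key=lambda r: (-r.mda, -r.mdg, r.gene_id))
    if mode == "top_k":
        if len(ranked) < config.panel_size:
            logger.warning(
                "only %d genes available for a panel of %d",
                len(ranked),
                config.panel_size,
            )
        chosen = ranked[: config.panel_size]
    elif mode == "threshold":
        chosen = [
            r
            for r in ranked
            if r.mda >= config.mda_threshold and r.mdg > config.mdg_threshold
        ]
    else:
        raise ValueError("mode must be 'top_k' or 'threshold'")

    entries = []
    for r in chosen:
        d = direction.get(r.gene_id)
        if d is None:
            raise KeyError(f"gene {r.gene_id} missing from the DEG table")
        if d == "none":
            raise ValueError(
                f"gene {r.gene_id} has no screened direction; "
                "restrict the forest to DEGs before selection"
            )
        entries.append((r.gene_id, d))
    n_up = sum(1 for _, d in entries if d == "up")
    logger.info(
        "panel: %d genes (%d up, %d down)", len(entries), n_up, len(entries) - n_up
    )
    return GenePanel(entries)


def importance_frame(
    importances: list[ImportanceRecord], selected_ids=None
) -> pd.DataFrame:
    df = pd.DataFrame([r.__dict__ for r in importances])
    if selected_ids is not None:
        df["selected"] = df["gene_id"].isin(set(selected_ids))
    return df
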