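"""Direction-aware median dichotomization of panel genes (Gene_Score).

Each panel gene's expression is compared against its median across *all*
samples of the cohort being scored (cases and controls together).  An
up-regulated gene scores 1 when the sample's value is strictly above the
median and 0 otherwise; a down-regulated gene scores 0 when strictly above
and 1 otherwise (so equality with the median scores 1 for a down gene).
Because only ranks relative to the median matter, the scores are invariant
under any strictly monotone per-gene transform, which is what makes the
score portable across platforms with different intensity scales.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import ExpressionMatrix

logger = logging.getLogger("ucmps")

__all__ = [
    "GenePanel",
    "ScoreMatrix",
    "binarize",
    "intersect_panel",
    "read_panel",
    "write_panel",
    "read_scores",
    "write_scores",
]


@dataclass(frozen=True)
class GenePanel:
    """Ordered diagnostic panel: (gene_id, direction) with direction up/down."""

    entries: tuple[tuple[str, str], ...]

    def __init__(self, entries: Iterable[tuple[str, str]]):
        entries = tuple((str(g), str(d)) for g, d in entries)
        ids = [g for g, _ in entries]
        if len(set(ids)) != len(ids):
            raise ValueError("panel gene ids must be unique")
        bad = {d for _, d in entries} - {"up", "down"}
        if bad:
            raise ValueError(f"panel directions must be up/down, got {bad}")
        object.__setattr__(self, "entries", entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    @property
    def directions(self) -> dict[str, str]:
        return dict(self.entries)


@dataclass
class ScoreMatrix:
    """Samples x panel-genes binary Gene_Score matrix with outcome labels."""

    scores: pd.DataFrame
    labels: pd.Series
    panel: GenePanel

    def __post_init__(self) -> None:
        self.scores = self.scores.astype(int)
        if not set(np.unique(self.scores.to_numpy())) <= {0, 1}:
            raise ValueError("scores must be binary")
        if list(self.scores.columns) != self.panel.gene_ids:
            raise ValueError("score columns must match panel order")
        self.labels = pd.Series(self.labels, dtype=int).reindex(self.scores.index)
        if self.labels.isna().any():
            raise ValueError("every scored sample needs a label")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.index)


def binarize(mat: ExpressionMatrix, panel: GenePanel) -> ScoreMatrix:
    """Compute Gene_Scores for every sample against cohort medians.

    All panel genes must be present in ``mat``; run :func:`intersect_panel`
    first when scoring an external cohort.
    """
    missing = [g for g in panel.gene_ids if g not in mat.values.index]
    if missing:
        raise KeyError(f"panel genes absent from matrix: {missing[:5]}")
    sub = mat.values.loc[panel.gene_ids]           # genes x samples
    med = sub.median(axis=1)
    above = sub.gt(med, axis=0).T                  # samples x genes
    cols = {}
    for gid, direction in panel:
        cols[gid] = above[gid].astype(int) if direction == "up" else (~above[gid]).astype(int)
    scores = pd.DataFrame(cols, index=mat.sample_ids)[panel.gene_ids]
    return ScoreMatrix(scores, mat.labels, panel)


def intersect_panel(panel: GenePanel, available_genes: Iterable[str]) -> GenePanel:
    """Restrict a panel to the genes measured in another cohort.

    Order is preserved; an empty intersection is fatal.
    """
    avail = set(available_genes)
    kept = [(g, d) for g, d in panel if g in avail]
    if not kept:
        raise ValueError("no panel gene is present in the target cohort")
    if len(kept) < len(panel):
        logger.info(
            "panel intersection: %d of %d genes present", len(kept), len(panel)
        )
    return GenePanel(kept)


def read_panel(path: str | Path) -> GenePanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gene_id", "direction"} <= set(df.columns):
        raise ValueError(f"{path}: need gene_id and direction columns")
    return GenePanel(zip(df["gene_id"], df["direction"]))


def write_panel(panel: GenePanel, path: str | Path,
                extra: Mapping[str, Sequence[float]] | None = None) -> None:
    df = pd.DataFrame(panel.entries, columns=["gene_id", "direction"])
    for name, col in (extra or {}).items():
        df[name] = list(col)
    df.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> ScoreMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "label" not in df.columns:
        raise ValueError(f"{path}: missing label column")
    labels = df.pop("label")
    panel = GenePanel((g, "up") for g in df.columns)  # direction not stored
    return ScoreMatrix(df, labels, panel)


def write_scores(scores: ScoreMatrix, path: str | Path) -> None:
    out = scores.scores.copy()
    out["label"] = scores.labels
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")
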