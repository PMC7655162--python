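"""Reading, writing and basic curation of gene-by-sample expression data.

The on-disk dialect is deliberately minimal and mirrors what processed GEO
series look like once exported to text: a tab-separated matrix with gene (or
probe) identifiers in the first column and sample identifiers in the header
row, plus a two-column label file mapping each sample to ``case`` or
``control``.  Cases are coded 1 and controls 0 everywhere downstream.

Duplicate measurements of one gene (multiple microarray probes) are
collapsed by taking the per-sample median over the gene's probes; probes
with no gene assignment are dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("ucmps")

__all__ = [
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "read_labels",
    "read_probe_map",
    "collapse_probes",
]

_LABEL_CODES = {"case": 1, "control": 0, "1": 1, "0": 0}


@dataclass
class ExpressionMatrix:
    """A genes x samples numeric matrix with binary sample labels.

    Parameters
    ----------
    values
        DataFrame with gene identifiers as the index and sample identifiers
        as columns.  No missing entries are allowed.
    labels
        Integer series indexed like ``values.columns``; 1 = case,
        0 = control.
    scale
        ``"tpm_like"`` for linear non-negative abundances or
        ``"log_intensity"`` for already-log2 data.  Controls how fold
        changes are formed; the values themselves are taken as-is.
    """

    values: pd.DataFrame
    labels: pd.Series
    scale: str = "tpm_like"

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        self.values.index.name = None
        self.values.columns.name = None
        self.labels = pd.Series(self.labels, dtype=int)
        self.labels.index.name = None
        self.labels.name = None
        if self.scale not in ("tpm_like", "log_intensity"):
            raise ValueError(f"unknown expression scale {self.scale!r}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicated gene/probe identifiers: {list(dups)[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicated sample identifiers: {list(dups)[:5]}")
        if not self.labels.index.equals(self.values.columns):
            self.labels = self.labels.reindex(self.values.columns)
        if self.labels.isna().any():
            missing = self.labels.index[self.labels.isna()]
            raise ValueError(f"samples without labels: {list(missing)[:5]}")
        if not set(np.unique(self.labels)) <= {0, 1}:
            raise ValueError("labels must be coded case=1 / control=0")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_cases(self) -> int:
        return int((self.labels == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.labels == 0).sum())

    def case_values(self) -> pd.DataFrame:
        return self.values.loc[:, self.labels == 1]

    def control_values(self) -> pd.DataFrame:
        return self.values.loc[:, self.labels == 0]

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return ExpressionMatrix(
            self.values.loc[:, keep], self.labels.loc[keep], scale=self.scale
        )

    def require_both_classes(self) -> None:
        if self.n_cases == 0 or self.n_controls == 0:
            raise ValueError(
                f"need both classes: {self.n_cases} cases, {self.n_controls} controls"
            )


def read_labels(labels_path: str | Path) -> pd.Series:
    """Read a two-column sample/label TSV into a 0/1 integer series."""
    df = pd.read_csv(labels_path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{labels_path}: expected two columns (sample_id, label)")
    df = df.iloc[:, :2]
    df.columns = ["sample_id", "label"]
    if df["sample_id"].duplicated().any():
        dups = df["sample_id"][df["sample_id"].duplicated()].tolist()
        raise ValueError(f"{labels_path}: duplicate sample ids {dups[:5]}")
    coded = df["label"].str.strip().str.lower().map(_LABEL_CODES)
    if coded.isna().any():
        bad = df["label"][coded.isna()].unique()
        raise ValueError(
            f"{labels_path}: labels must be case/control (or 1/0), got {list(bad)[:5]}"
        )
    return pd.Series(coded.to_numpy(dtype=int), index=df["sample_id"].to_numpy())


def read_expression(
    matrix_path: str | Path,
    labels_path: str | Path,
    scale: str = "tpm_like",
) -> ExpressionMatrix:
    """Load a TSV expression matrix and its label file.

    Samples are restricted to those present in both files, in the matrix's
    column order.  Rows containing missing values are dropped and counted in
    the log.  Non-numeric cells, duplicated sample columns and an empty
    sample intersection are fatal.
    """
    with open(matrix_path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({s for s in header if header.count(s) > 1})
        raise ValueError(f"{matrix_path}: duplicated sample columns {dups[:5]}")
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
    for col in raw.columns:
        if raw[col].dtype == object:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = raw.index[coerced.isna() & raw[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{matrix_path}: non-numeric value at row {bad[0]!r}, column {col!r}"
                )
            raw[col] = coerced

    labels = read_labels(labels_path)
    common = [s for s in raw.columns if s in set(labels.index)]
    if not common:
        raise ValueError("no overlapping samples between matrix and labels")
    dropped_samples = (set(raw.columns) | set(labels.index)) - set(common)
    if dropped_samples:
        logger.warning(
            "dropping %d sample(s) absent from matrix or labels: %s",
            len(dropped_samples),
            sorted(dropped_samples)[:5],
        )
    raw = raw.loc[:, common]

    n_na = int(raw.isna().any(axis=1).sum())
    if n_na:
        logger.warning("dropping %d gene row(s) with missing values", n_na)
        raw = raw.dropna(axis=0)

    return ExpressionMatrix(raw, labels.loc[common], scale=scale)


def write_expression(mat: ExpressionMatrix, matrix_path: str | Path,
                     labels_path: str | Path | None = None) -> None:
    """Write the matrix (and optionally labels) back to TSV.

    Values are written with enough digits (repr round-trip) that reading the
    file back reproduces them exactly.
    """
    out = mat.values.copy()
    out.index.name = "gene_id"
    out.to_csv(matrix_path, sep="\t", float_format="%.17g")
    if labels_path is not None:
        lab = pd.DataFrame(
            {
                "sample_id": mat.sample_ids,
                "label": ["case" if v == 1 else "control" for v in mat.labels],
            }
        )
        lab.to_csv(labels_path, sep="\t", index=False)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column probe-to-gene TSV into a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (probe_id, gene_id)")
    df = df.iloc[:, :2]
    df.columns = ["probe_id", "gene_id"]
    if df["probe_id"].duplicated().any():
        raise ValueError(f"{path}: a probe maps to more than one gene")
    return dict(zip(df["probe_id"], df["gene_id"]))


def collapse_probes(
    raw: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by per-sample median.

    Probes absent from ``probe_map`` are removed.  Raises if no probe in the
    matrix is covered by the map.
    """
    mapped = [p for p in raw.gene_ids if p in probe_map]
    if not mapped:
        raise ValueError("no probe in the matrix is covered by the probe map")
    n_removed = len(raw.gene_ids) - len(mapped)
    if n_removed:
        logger.info("removing %d unmapped probe(s)", n_removed)
    sub = raw.values.loc[mapped]
    genes = pd.Index([probe_map[p] for p in mapped], name="gene_id")
    collapsed = sub.groupby(genes, sort=False).median()
    return ExpressionMatrix(collapsed, raw.labels, scale=raw.scale)
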