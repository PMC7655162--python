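"""Per-gene case/control differential-expression screen.

Each gene is tested with a two-sided Welch (unequal-variance) t-test and the
raw p-values are Benjamini-Hochberg adjusted across genes.  A gene is called
up-regulated when ``log2FC > threshold`` and ``p_adj < alpha`` (strict
inequalities; a gene landing exactly on either cutoff is not called), and
down-regulated symmetrically.

Fold changes are formed per the data's scale: for linear, non-negative
abundances (TPM-like) the contrast is ``log2((mean_case + c) /
(mean_control + c))`` with pseudocount ``c`` guarding against zero means;
for already-log2 intensities it is the plain difference of group means.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .io_core import ExpressionMatrix

logger = logging.getLogger("ucmps")

__all__ = [
    "DegRecord",
    "log2_fold_change",
    "welch_t_test",
    "bh_adjust",
    "screen_degs",
    "deg_frame",
]

_VAR_FLOOR = 1e-12


@dataclass(frozen=True)
class DegRecord:
    gene_id: str
    log2fc: float
    p_raw: float
    p_adj: float
    direction: str  # up | down | none


def log2_fold_change(
    case_values, control_values, pseudocount: float = 1.0, scale: str = "tpm_like"
) -> float:
    """Case-vs-control contrast on the log2 scale (see module docstring)."""
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("both groups need at least one value")
    if scale == "tpm_like":
        if (case_values < 0).any() or (control_values < 0).any():
            raise ValueError("tpm_like values must be non-negative")
        return float(
            np.log2(
                (case_values.mean() + pseudocount)
                / (control_values.mean() + pseudocount)
            )
        )
    if scale == "log_intensity":
        return float(case_values.mean() - control_values.mean())
    raise ValueError(f"unknown scale {scale!r}")


def _welch_arrays(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Welch t along the last axis; handles zero-variance genes."""
    n1, n0 = case.shape[-1], control.shape[-1]
    if n1 < 2 or n0 < 2:
        raise ValueError("both groups need at least two values")
    m1, m0 = case.mean(-1), control.mean(-1)
    v1, v0 = case.var(-1, ddof=1), control.var(-1, ddof=1)
    se2 = v1 / n1 + v0 / n0
    se2_f = np.maximum(se2, _VAR_FLOOR)
    t = (m1 - m0) / np.sqrt(se2_f)
    with np.errstate(divide="ignore", invalid="ignore"):
        df = se2_f**2 / (
            np.maximum(v1, _VAR_FLOOR) ** 2 / (n1**2 * (n1 - 1))
            + np.maximum(v0, _VAR_FLOOR) ** 2 / (n0**2 * (n0 - 1))
        )
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # both groups constant and equal: no evidence against the null
    degenerate = (se2 == 0) & (m1 == m0)
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, np.minimum(p, 1.0))
    return t, p


def welch_t_test(case_values, control_values) -> tuple[float, float]:
    """Two-sided Welch t-test with Welch-Satterthwaite degrees of freedom."""
    case = np.atleast_2d(np.asarray(case_values, dtype=float))
    control = np.atleast_2d(np.asarray(control_values, dtype=float))
    t, p = _welch_arrays(case, control)
    return float(t[0]), float(p[0])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D vector of p-values")
    if ((p < 0) | (p > 1) | np.isnan(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def screen_degs(mat: ExpressionMatrix, config: PipelineConfig) -> list[DegRecord]:
    """Run the DEG screen over every gene of the matrix."""
    mat.require_both_classes()
    case = mat.case_values().to_numpy()
    control = mat.control_values().to_numpy()

    if mat.scale == "tpm_like":
        if (case < 0).any() or (control < 0).any():
            raise ValueError("tpm_like matrix contains negative values")
        log2fc = np.log2(
            (case.mean(1) + config.pseudocount) / (control.mean(1) + config.pseudocount)
        )
    else:
        log2fc = case.mean(1) - control.mean(1)

    _, p_raw = _welch_arrays(case, control)
    p_adj = bh_adjust(p_raw)

    sig = p_adj < config.alpha
    direction = np.where(
        sig & (log2fc > config.log2fc_threshold),
        "up",
        np.where(sig & (log2fc < -config.log2fc_threshold), "down", "none"),
    )
    records = [
        DegRecord(g, float(fc), float(pr), float(pa), str(d))
        for g, fc, pr, pa, d in zip(mat.gene_ids, log2fc, p_raw, p_adj, direction)
    ]
    n_up = int((direction == "up").sum())
    n_down = int((direction == "down").sum())
    logger.info("DEG screen: %d up, %d down of %d genes", n_up, n_down, len(records))
    return records


def deg_frame(records: list[DegRecord]) -> pd.DataFrame:
    """Tabular (volcano-ready) view: adds -log10 adjusted p."""
    df = pd.DataFrame([r.__dict__ for r in records])
    with np.errstate(divide="ignore"):
        df["neg_log10_p_adj"] = -np.log10(df["p_adj"])
    return df
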