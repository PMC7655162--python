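"""Gene weights from a compact feed-forward classifier on Gene_Scores.

The network is intentionally small: one input unit per panel gene, a single
ReLU hidden layer (default 8 units), and a 2-unit softmax output trained
against the one-hot case/control outcome with categorical cross-entropy and
the Adam optimizer.  It is implemented directly in numpy so that training is
bit-reproducible for a fixed seed.

After training, each gene's **Gene_Weight** is the maximum of its
input-to-hidden connection weights over hidden units (raw signed maximum by
default; with ReLU units and 0/1 inputs the informative genes' weights trend
positive).  An absolute-maximum variant is available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnnSpec
from .scoring import GenePanel, ScoreMatrix

logger = logging.getLogger("ucmps")

__all__ = [
    "AnnSpec",
    "WeightedPanel",
    "GeneScoreNet",
    "train_ann",
    "extract_gene_weights",
    "load_reference_weights",
    "reference_weights_path",
    "read_weights",
    "write_weights",
]


@dataclass
class WeightedPanel:
    """A gene panel plus one Gene_Weight per gene, order-aligned."""

    panel: GenePanel
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.panel),):
            raise ValueError("need exactly one weight per panel gene")
        if not np.isfinite(self.weights).all():
            raise ValueError("weights must be finite")

    def as_series(self) -> pd.Series:
        return pd.Series(self.weights, index=self.panel.gene_ids, name="gene_weight")


def _softmax(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


class GeneScoreNet:
    """input -> ReLU hidden -> 2-unit softmax, trained with Adam.

    Exposes the input-to-hidden weight matrix ``w_hidden`` of shape
    (n_inputs, hidden_units) for weight extraction, and the per-epoch mean
    cross-entropy in ``loss_history``.
    """

    def __init__(self, n_inputs: int, spec: AnnSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.rng_seed)
        h = spec.hidden_units
        lim1 = np.sqrt(6.0 / (n_inputs + h))
        lim2 = np.sqrt(6.0 / (h + 2))
        self.w1 = rng.uniform(-lim1, lim1, size=(n_inputs, h))
        self.b1 = np.zeros(h)
        self.w2 = rng.uniform(-lim2, lim2, size=(h, 2))
        self.b2 = np.zeros(2)
        self._rng = rng
        self.loss_history: list[float] = []

    @property
    def w_hidden(self) -> np.ndarray:
        return self.w1

    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hidden = np.maximum(X @ self.w1 + self.b1, 0.0)
        return hidden, _softmax(hidden @ self.w2 + self.b2)

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return self._forward(np.asarray(X, dtype=float))[1]

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.predict_proba(X).argmax(axis=1)

    def accuracy(self, X: np.ndarray, y: np.ndarray) -> float:
        return float((self.predict(X) == np.asarray(y)).mean())

    def loss(self, X: np.ndarray, y: np.ndarray) -> float:
        proba = self.predict_proba(X)
        eps = 1e-12
        return float(-np.log(proba[np.arange(len(y)), np.asarray(y)] + eps).mean())

    def fit(self, X: np.ndarray, y: np.ndarray) -> "GeneScoreNet":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        n = len(y)
        onehot = np.eye(2)[y]
        spec = self.spec
        params = [self.w1, self.b1, self.w2, self.b2]
        m = [np.zeros_like(p) for p in params]
        v = [np.zeros_like(p) for p in params]
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        step = 0
        self.loss_history.append(self.loss(X, y))
        for _ in range(spec.epochs):
            order = self._rng.permutation(n)
            for start in range(0, n, spec.batch_size):
                idx = order[start : start + spec.batch_size]
                xb, tb = X[idx], onehot[idx]
                hidden = np.maximum(xb @ self.w1 + self.b1, 0.0)
                proba = _softmax(hidden @ self.w2 + self.b2)
                # cross-entropy + softmax gradient
                dz2 = (proba - tb) / len(idx)
                grads = [None] * 4
                grads[2] = hidden.T @ dz2
                grads[3] = dz2.sum(axis=0)
                dh = (dz2 @ self.w2.T) * (hidden > 0)
                grads[0] = xb.T @ dh
                grads[1] = dh.sum(axis=0)
                step += 1
                for i, (p, g) in enumerate(zip(params, grads)):
                    m[i] = beta1 * m[i] + (1 - beta1) * g
                    v[i] = beta2 * v[i] + (1 - beta2) * g * g
                    mhat = m[i] / (1 - beta1**step)
                    vhat = v[i] / (1 - beta2**step)
                    p -= spec.learning_rate * mhat / (np.sqrt(vhat) + eps)
            self.loss_history.append(self.loss(X, y))
        return self


def train_ann(scores: ScoreMatrix, spec: AnnSpec | None = None) -> GeneScoreNet:
    """Train the gene-weight network on a binary Gene_Score matrix."""
    spec = spec or AnnSpec()
    X = scores.scores.to_numpy(dtype=float)
    y = scores.labels.to_numpy()
    if len(np.unique(y)) < 2 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ValueError("need at least two samples in each class")
    if not set(np.unique(X)) <= {0.0, 1.0}:
        raise ValueError("Gene_Scores must be binary")
    net = GeneScoreNet(X.shape[1], spec).fit(X, y)
    logger.info(
        "ANN: loss %.4f -> %.4f, training accuracy %.3f",
        net.loss_history[0],
        net.loss_history[-1],
        net.accuracy(X, y),
    )
    return net


def extract_gene_weights(
    net: GeneScoreNet, panel: GenePanel, use_abs: bool = False
) -> WeightedPanel:
    """Gene_Weight = (signed) maximum input-to-hidden weight per gene."""
    w = net.w_hidden
    if w.shape[0] != len(panel):
        raise ValueError(
            f"network has {w.shape[0]} input units but panel has {len(panel)} genes"
        )
    weights = np.abs(w).max(axis=1) if use_abs else w.max(axis=1)
    return WeightedPanel(panel, weights)


def read_weights(path: str | Path) -> WeightedPanel:
    """Read a two-column gene_id / gene_weight TSV into a WeightedPanel.

    Directions are not stored in weight tables; genes are loaded as "up"
    placeholders, which the mPS summation never consults.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str})
    if df.shape[0] == 0:
        raise ValueError(f"{path}: empty weight table")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected columns gene_id, gene_weight")
    df = df.iloc[:, :2]
    df.columns = ["gene_id", "gene_weight"]
    if df["gene_id"].duplicated().any():
        dups = df["gene_id"][df["gene_id"].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate gene ids {dups[:5]}")
    weights = pd.to_numeric(df["gene_weight"], errors="coerce")
    if weights.isna().any():
        bad = df["gene_id"][weights.isna()].tolist()
        raise ValueError(f"{path}: non-numeric weight for {bad[:5]}")
    panel = GenePanel((g, "up") for g in df["gene_id"])
    return WeightedPanel(panel, weights.to_numpy())


load_reference_weights = read_weights


def reference_weights_path() -> Path:
    """Path of the packaged 30-gene ulcerative-colitis reference weights.

    This is the published diagnostic panel's Gene_Weight table (29 up- and 1
    down-regulated colonic genes), shipped as a worked-example fixture for
    the mPS summation.
    """
    return Path(resources.files("ucmps").joinpath("data/table3_weights.tsv"))


def write_weights(weighted: WeightedPanel, path: str | Path) -> None:
    weighted.as_series().rename_axis("gene_id").reset_index().to_csv(
        path, sep="\t", index=False
    )
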