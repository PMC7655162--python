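# ucmps

A molecular prognostic score (mPS) pipeline for case/control transcriptomics,
built around the diagnostic-model construction strategy used for ulcerative
colitis (UC): screen differentially expressed genes (DEGs), rank them with a
random forest, dichotomize panel-gene expression at the cohort median,
learn per-gene weights with a small feed-forward network, and sum weighted
binary scores into one diagnostic score per sample.

It is aimed at researchers who want to build or audit composite
gene-panel classifiers from a labeled gene-by-sample expression matrix
(TPM-like or log-intensity), including a full synthetic-data harness so
every stage can be exercised and validated without access to the original
cohorts.

## Method

Given expression matrix `X` (genes × samples) with labels `y` (case = 1,
control = 0):

1. **DEG screen** — per gene, a two-sided Welch *t*-test and a fold change
   `log2FC = log2((mean_case + c)/(mean_control + c))` (or a difference of
   means on already-log2 data). Genes with `|log2FC| > 2` and
   Benjamini–Hochberg adjusted `p < 0.05` (both strict) are called up/down.
2. **Panel selection** — a bagged ensemble of CART trees ranks DEGs by
   out-of-bag permutation importance (mean decrease in accuracy, scaled by
   its standard error) with mean decrease in Gini as tie-breaker; the
   top-*k* genes (default 30) form the panel. Absolute cutoffs
   (MDA ≥ 3.56, MDG > 0.53) are available as an alternative mode.
3. **Gene_Score** — for each panel gene, each sample scores 1 if its
   expression is strictly above the gene's median across all cohort samples
   (up-regulated gene) or at/below it (down-regulated gene), else 0.
4. **Gene_Weight** — a one-hidden-layer ReLU network with a 2-unit softmax
   output is trained on the binary scores (cross-entropy, Adam); the weight
   of gene *g* is the maximum of its input-to-hidden connection weights.
5. **mPS** — `mPS(s) = Σ_g Gene_Score(s, g) · Gene_Weight(g)`, evaluated as
   a ranking by ROC-AUC (Mann–Whitney pairwise statistic, ties half) and
   PR-AUC (average-precision step convention).

Cross-cohort validation intersects the panel with the second cohort's
genes, re-binarizes against that cohort's own medians, and either re-learns
weights there (`retrain`, the published protocol — note it leaks evaluation
labels and flatters the AUC) or applies the frozen training weights
(`transfer`, the leakage-free alternative).

## Worked example

```sh
ucmps simulate --cases 30 --controls 30 --null 400 --up 20 --down 10 \
    --effect 4.0 --seed 7 --out demo
ucmps run-all --matrix demo/matrix.tsv --labels demo/labels.tsv \
    --seed 7 --out demo/run
```

prints

```
wrote cohort (430 genes x 60 samples) to demo
ROC-AUC 1.0000, PR-AUC 1.0000 -> demo/run
```

The simulated cohort plants 20 up- and 10 down-regulated genes at
|log2FC| = 4 over 400 null genes. `demo/run/` then contains the screened
DEG table, forest importances, the 30-gene panel, the binary Gene_Score
sheet, the learned weights, per-sample mPS values and `metrics.json`; with
this much planted signal the mPS separates cases from controls perfectly
(ROC-AUC and PR-AUC of 1.0). In `demo/run/mps.tsv` the first case sample
scores mPS ≈ 10.36 — the sum of the learned weights of the panel genes it
scores 1 on.

The same stages are available in the library API
(`ucmps.run_pipeline`, `ucmps.validate_external`, `ucmps.roc_auc`, ...),
and a published 30-gene UC reference panel with its weights ships as a
packaged fixture (`ucmps.reference_weights_path()`): a sample scoring 1 on
every panel gene has mPS 106.0675; one scoring only on MMP1 has mPS 4.5608.

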