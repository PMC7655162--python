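# Methods

## Model and procedure

The package builds a composite diagnostic score for a binary case/control
contrast from one gene-by-sample expression matrix. The chain is:

DEG screen → random-forest importance ranking → median-dichotomized binary
Gene_Scores → feed-forward-network gene weights → mPS (weighted score sum)
→ ROC-AUC / PR-AUC evaluation, with an external-cohort validation protocol.

The key assumptions are (a) the case/control contrast is expressed in a
modest number of genes with large fold changes, so a univariate screen plus
a forest ranking finds them; (b) per-gene information survives reduction to
one bit (above/below the cohort median), which buys platform independence
at the cost of within-cohort resolution; and (c) sample ranking, not
calibrated probability, is the deliverable — only ROC/PR metrics are
attached, and no mPS decision threshold is defined.

## Stage details and defaults

**DEG screen.** Welch's unequal-variance t-test, two-sided, with
Welch–Satterthwaite degrees of freedom; this is the default behavior of the
standard R `t.test` the original analysis most plausibly used. Fold change
on linear (TPM-like) data is the ratio of group means with pseudocount 1
(configurable) to guard zero means; on log-intensity data it is the
difference of group means. Thresholds `|log2FC| > 2` and BH-adjusted
`p < 0.05` are strict inequalities. Degenerate genes: if both groups are
constant and equal the gene gets t = 0, p = 1; otherwise a variance floor
of 1e-12 prevents division by zero. Multiple-testing correction is applied
across genes once, at the screening stage only.

**Forest importances.** 500 trees (the classical package default), sqrt(p)
candidate features per split, bootstrap resampling implemented explicitly
so that out-of-bag (OOB) sets are available per tree. MDA is the per-tree
drop in OOB accuracy after permuting one feature among the OOB samples,
averaged over trees and divided by its standard error over trees — the
"scaled" convention, the only scale on which absolute thresholds like 3.56
are meaningful (raw accuracy drops are ≤ 1). MDG is the total
sample-count-weighted Gini-impurity decrease at nodes splitting on the
gene, averaged over trees. Importances are deterministic given the seed;
only rank stability, not cross-backend bit-identity, is promised. Top-k
(k = 30) selection is the primary mode because absolute importance cutoffs
are dataset-specific; ties break by MDG, then lexical gene id, so selection
is fully deterministic.

**Gene_Score.** The median is taken over all samples of the cohort being
scored — cases and controls together — because the validation protocol
re-derives scores inside the external cohort; frozen training medians for
truly prospective use can be passed by binarizing with a panel against the
training matrix and transferring the cut-points upstream of this package.
Equality with the median scores 0 for an up gene and 1 for a down gene
("strictly above" is the only comparison used). Median of an even count is
the mean of the two central order statistics. Scores are invariant under
any strictly monotone per-gene transform.

**Gene-weight network.** One ReLU hidden layer (default 8 units) feeding a
2-unit softmax; categorical cross-entropy against the one-hot outcome;
Adam (β₁ = 0.9, β₂ = 0.999) at learning rate 1e-3; batch size 16; 200
epochs; Glorot-uniform initialization; implemented directly in numpy so
training is bit-reproducible for a fixed seed. A single hidden layer makes
the extraction rule — Gene_Weight = maximum input-to-hidden weight of the
gene — well defined. The signed maximum is the default (with ReLU and
one-hot targets, informative genes trend positive); an absolute-maximum
variant exists. No train/validation split is made within a cohort,
mirroring the original protocol; the extracted weights therefore describe
the fit, not generalization.

**mPS and metrics.** mPS is the plain weighted sum of binary scores, hence
linear in the weights and bounded by their sum when all weights are
non-negative. ROC-AUC is computed by midranks (exact under ties); PR-AUC
uses the average-precision step convention with tied scores processed as
one threshold group, because interpolated PR curves are biased upward.
Cases are the positive class everywhere.

**Validation modes.** `retrain` (default, matching the published protocol)
re-learns weights on the evaluation cohort and logs a prominent warning:
the evaluation labels leak into the weights and the reported AUCs are
optimistic. `transfer` applies the frozen training weights restricted to
the intersected panel and is the methodologically sound choice.

## Synthetic data

The generator is Gaussian on the log2 scale: gene baseline means are
Normal(6, 1.5) in log2 units, i.i.d. Normal(0, 1) log2 noise per
measurement, and planted genes shift cases by ±effect (default 3 log2
units). `tpm_like` output exponentiates (minus a pseudocount, floored at
0), giving skewed non-negative linear values; `log_intensity` keeps the
Gaussian values. Default group sizes (200 cases / 20 controls) mirror a
strongly imbalanced discovery cohort; the test harness mostly uses balanced
30/30 designs with effect 4, where screening should be near-perfect.

What the generator does **not** emulate: count noise (negative-binomial
overdispersion), library-size and batch effects, gene–gene correlation, and
platform-specific probe behavior beyond optional duplicated probes with
Gaussian jitter. Passing recovery tests on this model therefore shows the
pipeline's machinery is correct and self-consistent, not that the published
cohort-level numbers would be reproduced on real data.

## Numerical and design choices

- Probe collapse takes the per-sample median over a gene's probes; probes
  without a gene assignment are dropped. Collapse is idempotent and
  commutes with sample subsetting.
- Missing values: gene rows containing any NA are dropped at load time and
  counted in the log; no imputation.
- Labels are coded case = 1 / control = 0 throughout.
- Seeds: one pipeline seed deterministically derives stage seeds (forest,
  network) via fixed affine maps; `run-all` with a fixed seed is
  byte-reproducible on one backend.
- On the TPM-like scale per-gene values are lognormal, so the t-test is
  only asymptotically calibrated there; the null-calibration property is
  checked on the log-intensity scale where the generative model is exactly
  Gaussian.
- Problem sizes in the test-suite recovery checks are the package's own
  choices: screening/selection recovery uses 900-gene, 30 + 20-planted,
  30/30-sample cohorts over 20 seeds; end-to-end and transfer checks use 10
  seeds; the forest's raw-background ranking property uses a reduced
  300-gene, 15-planted design over 5 seeds. The informative-vs-null weight
  separation property trains at learning rate 0.01 so that the learned
  drift dominates the Glorot initialization noise floor within 200 epochs.

## Known limitations

- The binary Gene_Score discards within-cohort expression magnitude;
  cohorts with prevalence far from the training design change the median
  cut-point's meaning.
- MDA/MDG values are convention-dependent; absolute thresholds ported from
  other software or datasets should be used only with the scaled-MDA
  convention documented above.
- Retrain-mode validation is reported for protocol fidelity but is not an
  unbiased estimate of external performance; use transfer mode for that.
- Network weight extraction (max over hidden units) is a heuristic
  attribution, not a calibrated effect size; weights are comparable within
  one trained network only.
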