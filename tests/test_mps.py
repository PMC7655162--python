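import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ucmps import GenePanel, WeightedPanel, compute_mps, pr_auc, roc_auc
from ucmps.ann import load_reference_weights, reference_weights_path
from ucmps.scoring import ScoreMatrix

from conftest import brute_pr_auc, brute_roc_auc

# the 30 published Gene_Weight values, re-typed for an independent summation
REFERENCE_WEIGHTS = [
    3.1869, 3.0181, 3.7603, 4.5608, 3.0028, 3.0258, 3.6774, 3.0121, 3.0217,
    3.0115, 3.0328, 3.0119, 4.5567, 4.0558, 3.0259, 3.1662, 3.0118, 4.3368,
    3.0149, 3.2243, 4.3764, 3.1524, 1.1187, 3.7521, 4.2631, 4.7713, 4.6224,
    4.5594, 3.0244, 4.7128,
]


def _scores_for(weighted: WeightedPanel, rows: np.ndarray, labels) -> ScoreMatrix:
    genes = weighted.panel.gene_ids
    samples = [f"s{i}" for i in range(rows.shape[0])]
    return ScoreMatrix(
        pd.DataFrame(rows, index=samples, columns=genes),
        pd.Series(labels, index=samples),
        weighted.panel,
    )


class TestComputeMps:
    def test_all_zero_scores_give_zero(self):
        weighted = load_reference_weights(reference_weights_path())
        scores = _scores_for(weighted, np.zeros((3, 30), dtype=int), [1, 0, 0])
        assert (compute_mps(scores, weighted) == 0).all()

    def test_all_one_scores_sum_reference_weights(self):
        weighted = load_reference_weights(reference_weights_path())
        scores = _scores_for(weighted, np.ones((2, 30), dtype=int), [1, 0])
        expected = sum(REFERENCE_WEIGHTS)  # = 106.0675 by independent re-add
        assert np.allclose(compute_mps(scores, weighted), expected)
        assert expected == pytest.approx(106.0675, abs=1e-10)

    def test_single_gene_contribution(self):
        weighted = load_reference_weights(reference_weights_path())
        rows = np.zeros((1, 30), dtype=int)
        rows[0, weighted.panel.gene_ids.index("MMP1")] = 1
        scores = _scores_for(weighted, rows, [1])
        assert compute_mps(scores, weighted).iloc[0] == pytest.approx(4.5608)

    def test_linearity_in_weights(self):
        rng = np.random.default_rng(0)
        panel = GenePanel([(f"g{i}", "up") for i in range(5)])
        w = WeightedPanel(panel, rng.uniform(1, 3, 5))
        rows = rng.integers(0, 2, size=(8, 5))
        scores = _scores_for(w, rows, [1, 0] * 4)
        doubled = WeightedPanel(panel, 2 * w.weights)
        assert np.allclose(
            compute_mps(scores, doubled), 2 * compute_mps(scores, w)
        )

    def test_zero_weight_gene_changes_nothing(self):
        rng = np.random.default_rng(1)
        panel = GenePanel([(f"g{i}", "up") for i in range(4)])
        w = WeightedPanel(panel, [1.0, 2.0, 3.0, 4.0])
        rows = rng.integers(0, 2, size=(6, 4))
        scores = _scores_for(w, rows, [1, 0, 1, 0, 1, 0])
        base = compute_mps(scores, w)

        big_panel = GenePanel(list(panel.entries) + [("extra", "up")])
        w2 = WeightedPanel(big_panel, [1.0, 2.0, 3.0, 4.0, 0.0])
        rows2 = np.hstack([rows, rng.integers(0, 2, size=(6, 1))])
        scores2 = _scores_for(w2, rows2, scores.labels.tolist())
        assert np.allclose(compute_mps(scores2, w2), base)

    def test_gene_set_mismatch_fatal(self):
        panel = GenePanel([("gA", "up")])
        w = WeightedPanel(panel, [1.0])
        other = WeightedPanel(GenePanel([("gB", "up")]), [1.0])
        scores = _scores_for(w, np.ones((2, 1), dtype=int), [1, 0])
        with pytest.raises(KeyError, match="differ"):
            compute_mps(scores, other)


class TestRocAuc:
    def test_pairwise_example(self):
        assert roc_auc([0.9, 0.8, 0.7, 0.85], [1, 1, 0, 0]) == pytest.approx(0.75)

    def test_perfect_separation(self):
        assert roc_auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_half(self):
        assert roc_auc([3, 3, 3, 3], [1, 1, 0, 0]) == 0.5

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="both classes"):
            roc_auc([1, 2], [1, 1])

    def test_negation_symmetry_without_ties(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            n = int(rng.integers(4, 12))
            pred = rng.permutation(n).astype(float)  # distinct scores
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(pred, labels) + roc_auc(-pred, labels) == pytest.approx(1.0)


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([5, 6, 1, 2], [1, 1, 0, 0]) == 1.0

    def test_all_ties_give_prevalence(self):
        assert pr_auc([3, 3, 3, 3, 3], [1, 1, 0, 0, 0]) == pytest.approx(0.4)

    def test_top_ranked_single_case(self):
        assert pr_auc([0.9, 0.8, 0.1], [1, 0, 0]) == 1.0

    def test_no_cases_fatal(self):
        with pytest.raises(ValueError, match="case"):
            pr_auc([1, 2], [0, 0])


class TestMetricOracles:
    @settings(max_examples=300, derandomize=True)
    @given(st.data())
    def test_both_metrics_match_brute_force(self, data):
        n = data.draw(st.integers(3, 12))
        # small integer scores force plenty of ties
        pred = data.draw(
            st.lists(st.integers(0, 4), min_size=n, max_size=n).map(np.array)
        )
        labels = data.draw(
            st.lists(st.integers(0, 1), min_size=n, max_size=n).map(np.array)
        )
        if labels.sum() == 0 or labels.sum() == n:
            return
        assert roc_auc(pred, labels) == pytest.approx(
            brute_roc_auc(pred, labels), abs=1e-12
        )
        assert pr_auc(pred, labels) == pytest.approx(
            brute_pr_auc(pred, labels), abs=1e-12
        )

    def test_matches_sklearn_on_random_instances(self):
        from sklearn.metrics import average_precision_score, roc_auc_score

        rng = np.random.default_rng(3)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            pred = rng.normal(size=n)
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(pred, labels) == pytest.approx(
                roc_auc_score(labels, pred), abs=1e-12
            )
            assert pr_auc(pred, labels) == pytest.approx(
                average_precision_score(labels, pred), abs=1e-12
            )
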