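import numpy as np
import pandas as pd
import pytest

from ucmps import AnnSpec, GenePanel, extract_gene_weights, train_ann
from ucmps.ann import GeneScoreNet, load_reference_weights, reference_weights_path
from ucmps.scoring import ScoreMatrix


def _score_matrix(X: np.ndarray, y: np.ndarray, genes=None) -> ScoreMatrix:
    genes = genes or [f"g{i}" for i in range(X.shape[1])]
    samples = [f"s{i}" for i in range(X.shape[0])]
    panel = GenePanel([(g, "up") for g in genes])
    return ScoreMatrix(
        pd.DataFrame(X, index=samples, columns=genes),
        pd.Series(y, index=samples),
        panel,
    )


def _random_scores(n=40, p=6, seed=0, informative=1):
    rng = np.random.default_rng(seed)
    y = np.array([1, 0] * (n // 2))
    X = rng.integers(0, 2, size=(n, p))
    X[:, :informative] = y[:, None]
    return _score_matrix(X, y)


class TestTrainAnn:
    def test_weight_matrix_shape_contract(self):
        scores = _random_scores(p=6)
        net = train_ann(scores, AnnSpec(hidden_units=4, epochs=5, rng_seed=0))
        assert net.w_hidden.shape == (6, 4)

    def test_final_loss_below_initial(self):
        scores = _random_scores()
        net = train_ann(scores, AnnSpec(epochs=30, rng_seed=1))
        assert net.loss_history[-1] < net.loss_history[0]

    def test_linearly_separable_reaches_perfect_accuracy(self):
        scores = _random_scores(informative=1)
        net = train_ann(scores, AnnSpec(rng_seed=2))  # default epochs
        X = scores.scores.to_numpy(dtype=float)
        assert net.accuracy(X, scores.labels.to_numpy()) == 1.0

    def test_reproducible_given_seed(self):
        scores = _random_scores()
        spec = AnnSpec(epochs=20, rng_seed=5)
        a = train_ann(scores, spec).w_hidden
        b = train_ann(scores, spec).w_hidden
        assert np.array_equal(a, b)

    def test_single_class_fatal(self):
        X = np.ones((10, 3), dtype=int)
        with pytest.raises(ValueError, match="each class"):
            train_ann(_score_matrix(X, np.ones(10, dtype=int)))

    def test_non_binary_scores_fatal(self):
        scores = _random_scores()
        scores.scores.iloc[0, 0] = 2  # corrupt after construction
        with pytest.raises(ValueError, match="binary"):
            train_ann(scores)


class TestExtractGeneWeights:
    def test_max_over_hidden_units(self):
        net = GeneScoreNet(2, AnnSpec(hidden_units=3, rng_seed=0))
        net.w1 = np.array([[-0.2, 0.7, 0.1], [0.5, -0.9, 0.2]])
        panel = GenePanel([("gA", "up"), ("gB", "down")])
        weighted = extract_gene_weights(net, panel)
        assert weighted.weights.tolist() == [0.7, 0.5]

    def test_abs_max_variant(self):
        net = GeneScoreNet(1, AnnSpec(hidden_units=2, rng_seed=0))
        net.w1 = np.array([[-0.9, 0.3]])
        weighted = extract_gene_weights(net, GenePanel([("g", "up")]), use_abs=True)
        assert weighted.weights.tolist() == [0.9]

    def test_single_hidden_unit_degenerate_max(self):
        net = GeneScoreNet(1, AnnSpec(hidden_units=1, rng_seed=0))
        net.w1 = np.array([[0.42]])
        weighted = extract_gene_weights(net, GenePanel([("g", "up")]))
        assert weighted.weights[0] == pytest.approx(0.42)

    def test_panel_size_mismatch_fatal(self):
        net = GeneScoreNet(3, AnnSpec(rng_seed=0))
        with pytest.raises(ValueError, match="input units"):
            extract_gene_weights(net, GenePanel([("g", "up")]))

    def test_gene_permutation_equivariance(self):
        # permuting the network's input dimension together with the panel
        # permutes the extracted weights identically
        scores = _random_scores(p=5, seed=3)
        spec = AnnSpec(epochs=15, rng_seed=7)
        net = train_ann(scores, spec)
        w = extract_gene_weights(net, scores.panel).as_series()

        perm = [3, 0, 4, 1, 2]
        net.w1 = net.w1[perm]
        shuffled = GenePanel([scores.panel.entries[i] for i in perm])
        w2 = extract_gene_weights(net, shuffled).as_series()
        assert np.allclose(w.sort_index(), w2.sort_index())

    def test_informative_genes_outweigh_null_genes(self):
        # lr high enough that the learned drift dominates the Glorot
        # initialization noise floor shared by the null genes
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            n, k, p = 60, 3, 15
            y = np.array([1, 0] * (n // 2))
            X = rng.integers(0, 2, size=(n, p))
            X[:, :k] = y[:, None]
            scores = _score_matrix(X, y)
            net = train_ann(
                scores, AnnSpec(epochs=200, learning_rate=0.01, rng_seed=seed)
            )
            w = extract_gene_weights(net, scores.panel).weights
            null_median = np.median(w[k:])
            hits += bool((w[:k] > null_median).all())
        assert hits >= 18  # >= 90% of seeds


class TestReferenceWeights:
    def test_packaged_panel_values(self):
        weighted = load_reference_weights(reference_weights_path())
        s = weighted.as_series()
        assert len(s) == 30
        assert s["MMP1"] == pytest.approx(4.5608)
        assert s["HCG4P11"] == pytest.approx(1.1187)
        assert s.idxmin() == "HCG4P11"

    def test_duplicate_gene_fatal(self, tmp_path):
        f = tmp_path / "w.tsv"
        f.write_text("gene_id\tgene_weight\nA\t1.0\nA\t2.0\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_reference_weights(f)

    def test_non_numeric_weight_fatal(self, tmp_path):
        f = tmp_path / "w.tsv"
        f.write_text("gene_id\tgene_weight\nA\thigh\n")
        with pytest.raises(ValueError, match="non-numeric"):
            load_reference_weights(f)

    def test_empty_file_fatal(self, tmp_path):
        f = tmp_path / "w.tsv"
        f.write_text("gene_id\tgene_weight\n")
        with pytest.raises(ValueError, match="empty"):
            load_reference_weights(f)
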