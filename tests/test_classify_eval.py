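"""Confusion matrices, balanced accuracy, report tables, heads, projection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnporigin.classify_eval import (
    ConfusionMatrix,
    balanced_accuracy,
    balanced_accuracy_from_recalls,
    confusion,
    project_2d,
    round2,
    table_report,
    train_head,
)
from mnporigin.encoder import EmbeddingTable, extract_embeddings


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self):
        cm = confusion([0, 1, 2, 0], [0, 1, 2, 0])
        assert np.array_equal(cm.counts, np.diag([2, 1, 1]))

    def test_worked_example(self):
        cm = confusion([0, 1, 2], [1, 1, 2])
        assert cm.counts[0, 1] == 1 and cm.counts[1, 1] == 1 and cm.counts[2, 2] == 1

    def test_matches_bruteforce_tally_on_random_pairs(self):
        rng = np.random.default_rng(0)
        t = rng.integers(0, 3, 50)
        p = rng.integers(0, 3, 50)
        cm = confusion(t, p)
        for i in range(3):
            for j in range(3):
                assert cm.counts[i, j] == int(np.sum((t == i) & (p == j)))
        assert cm.total == 50

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion([0, 1], [0])


class TestBalancedAccuracy:
    def test_reported_pretrained_gbt_value(self):
        assert round2(balanced_accuracy_from_recalls([73.00, 89.68, 93.99])) == 85.56

    def test_reported_raw_gcn_value(self):
        assert round2(balanced_accuracy_from_recalls([93.64, 74.10, 85.18])) == 84.31

    def test_perfect_classifier_scores_100(self):
        cm = ConfusionMatrix(np.diag([5, 7, 9]))
        assert balanced_accuracy(cm) == 100.0

    def test_computed_from_recalls_per_definition(self):
        cm = ConfusionMatrix([[8, 1, 1], [2, 6, 2], [0, 0, 10]])
        expected = (8 / 10 + 6 / 10 + 10 / 10) / 3 * 100
        assert balanced_accuracy(cm) == pytest.approx(expected)

    def test_empty_class_error_names_the_class(self):
        cm = ConfusionMatrix([[5, 0, 0], [0, 0, 0], [0, 0, 5]])
        with pytest.raises(ValueError, match="Bacteria"):
            balanced_accuracy(cm)

    def test_invariant_to_class_rebalancing(self):
        base = np.array([[8, 1, 1], [2, 6, 2], [1, 1, 8]])
        scaled = base.copy()
        scaled[1] *= 5  # preserves row proportions, hence per-class recalls
        assert balanced_accuracy(ConfusionMatrix(base)) == pytest.approx(
            balanced_accuracy(ConfusionMatrix(scaled))
        )


class TestTableReport:
    def test_diagonal_matrix_all_100(self):
        rep = table_report(ConfusionMatrix(np.diag([4, 4, 4])))
        for i in range(3):
            assert rep.rows[i][i] == 100.00
            assert all(rep.rows[i][j] == 0.0 for j in range(3) if j != i)

    def test_row_percentage_arithmetic(self):
        cm = ConfusionMatrix([[80, 12, 8], [0, 10, 0], [0, 0, 10]])
        rep = table_report(cm)
        assert rep.rows[0] == {0: 80.00, 1: 12.00, 2: 8.00}

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        counts=st.lists(st.integers(0, 500), min_size=9, max_size=9).filter(
            lambda c: all(sum(c[3 * i: 3 * i + 3]) > 0 for i in range(3))
        )
    )
    def test_rows_sum_to_100_within_rounding(self, counts):
        cm = ConfusionMatrix(np.array(counts).reshape(3, 3))
        rep = table_report(cm)
        for i in range(3):
            assert sum(rep.rows[i].values()) == pytest.approx(100.00, abs=0.02)

    def test_named_dict_layout(self):
        rep = table_report(ConfusionMatrix(np.diag([1, 1, 1])))
        d = rep.as_dict()
        assert d["Balanced Acc"] == 100.0
        assert {"Ani Acc", "Ani to Bac", "Ani to Fun", "Bac Acc", "Fun Acc"} <= set(d)


class TestHeads:
    def _toy_emb(self):
        rng = np.random.default_rng(0)
        centers = np.array([[0, 0], [10, 0], [0, 10]])
        X, y = [], []
        for lab in range(3):
            pts = centers[lab] + rng.normal(scale=0.3, size=(20, 2))
            X.append(pts)
            y += [lab] * 20
        ids = [f"e{i}" for i in range(60)]
        return EmbeddingTable("last_ffn", ids, np.vstack(X)), dict(zip(ids, y))

    @pytest.mark.parametrize("kind", ["svm", "gbt"])
    def test_separable_toy_reaches_perfect_training_accuracy(self, kind):
        emb, labels = self._toy_emb()
        clf = train_head(emb, labels, kind, seed=0)
        pred = clf.predict(emb.vectors)
        assert (pred == np.array([labels[c] for c in emb.ids])).all()

    @pytest.mark.parametrize("kind", ["svm", "gbt"])
    def test_same_seed_identical_predictions(self, kind):
        emb, labels = self._toy_emb()
        p1 = train_head(emb, labels, kind, seed=3).predict(emb.vectors)
        p2 = train_head(emb, labels, kind, seed=3).predict(emb.vectors)
        assert np.array_equal(p1, p2)

    def test_single_class_input_rejected(self):
        emb, labels = self._toy_emb()
        with pytest.raises(ValueError, match="single class"):
            train_head(emb, {cid: 1 for cid in emb.ids}, "svm")

    def test_unknown_kind_rejected(self):
        emb, labels = self._toy_emb()
        with pytest.raises(ValueError):
            train_head(emb, labels, "forest")

    def test_learned_embeddings_beat_majority_rate(self, tuned_model, ds_small,
                                                   ds_medium):
        """GBT on last_FFN embeddings generalizes to unseen molecules."""
        train_emb = extract_embeddings(tuned_model, ds_small, "last_ffn")
        clf = train_head(train_emb, ds_small.labels(), "gbt", seed=0)
        mixed = ds_medium.ids[:40] + ds_medium.ids[200:230] + ds_medium.ids[300:330]
        holdout = ds_medium.subset(mixed)  # unseen generator draws, all classes
        test_emb = extract_embeddings(tuned_model, holdout, "last_ffn")
        acc = (clf.predict(test_emb.vectors) ==
               np.array([r.label for r in holdout])).mean()
        majority = max(ds_small.counts.values()) / len(ds_small)
        assert acc > majority


class TestProjection:
    def _emb(self, n=30, dim=6, seed=0):
        rng = np.random.default_rng(seed)
        return EmbeddingTable("mpn", [f"p{i}" for i in range(n)],
                              rng.normal(size=(n, dim)))

    @pytest.mark.parametrize("method", ["pca", "tsne"])
    def test_output_is_n_by_2(self, method):
        emb = self._emb()
        assert project_2d(emb, method, seed=0).shape == (30, 2)

    def test_pca_on_collinear_points_stays_collinear(self):
        t = np.linspace(0, 1, 10)[:, None]
        emb = EmbeddingTable("mpn", [f"p{i}" for i in range(10)],
                             t @ np.array([[1.0, 2.0, 3.0]]))
        xy = project_2d(emb, "pca", seed=0)
        assert np.allclose(xy[:, 1], 0.0, atol=1e-9)

    def test_seeded_repeatability(self):
        emb = self._emb()
        assert np.allclose(project_2d(emb, "tsne", seed=5),
                           project_2d(emb, "tsne", seed=5))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            project_2d(self._emb(n=2), "pca")
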