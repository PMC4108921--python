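"""Splitting, confusion matrices and sensitivity/specificity aggregation tests."""

import numpy as np
import pytest

import ctexture as ct
from ctexture.evaluate import (
    SplitSpec,
    leave_one_out_folds,
    merge_benign,
    run_separability_experiment,
    split_train_test,
)


def toy_set(n_per_class=10, classes=("a", "b", "c"), seed=0):
    rng = np.random.default_rng(seed)
    vectors, labels = [], []
    for i, c in enumerate(classes):
        vectors.extend(rng.normal(size=(n_per_class, 6)) + 12.0 * i)
        labels.extend([c] * n_per_class)
    return ct.LabeledPatternSet(vectors, labels, list(classes))


class TestSplit:
    def test_half_split_is_five_five_per_class(self):
        train, test = split_train_test(toy_set(10), SplitSpec(0.5, seed=1))
        for c in ("a", "b", "c"):
            assert train.labels.count(c) == 5
            assert test.labels.count(c) == 5

    def test_same_seed_identical_different_seed_differs(self):
        data = toy_set(10)
        t1a, _ = split_train_test(data, SplitSpec(0.5, seed=3))
        t1b, _ = split_train_test(data, SplitSpec(0.5, seed=3))
        t2, _ = split_train_test(data, SplitSpec(0.5, seed=4))
        assert t1a.labels == t1b.labels
        np.testing.assert_array_equal(t1a.to_matrix(), t1b.to_matrix())
        assert not np.array_equal(t1a.to_matrix(), t2.to_matrix())

    def test_leave_one_out_yields_n_singleton_folds(self):
        data = toy_set(4)
        folds = list(leave_one_out_folds(data))
        assert len(folds) == 12
        for train, test in folds:
            assert len(test) == 1 and len(train) == 11

    def test_single_sample_class_goes_train_only(self):
        data = ct.LabeledPatternSet(
            [np.zeros(6), np.ones(6), np.full(6, 2.0)], ["a", "a", "b"], ["a", "b"]
        )
        with pytest.warns(UserWarning, match="single sample"):
            train, test = split_train_test(data, SplitSpec(0.5, seed=0))
        assert "b" in train.labels and "b" not in test.labels

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(ct.LabeledPatternSet([], [], ["a"]), SplitSpec(0.5))


class TestConfusion:
    def test_perfect_predictions_identity(self):
        cm = ct.build_confusion(["white", "gray"], ["white", "gray"])
        i, j = cm.class_order.index("white"), cm.class_order.index("gray")
        assert cm.proportions[i, i] == 1.0 and cm.proportions[j, j] == 1.0

    def test_total_misassignment_single_column(self):
        cm = ct.build_confusion(["white"] * 4, ["black"] * 4)
        i, j = cm.class_order.index("white"), cm.class_order.index("black")
        assert cm.proportions[i, j] == 1.0

    def test_random_pairs_against_hand_tally(self):
        rng = np.random.default_rng(17)
        order = ("a", "b", "c")
        true = rng.choice(order, 20)
        pred = rng.choice(order, 20)
        cm = ct.build_confusion(list(true), list(pred), order)
        for i, t in enumerate(order):
            for j, p in enumerate(order):
                assert cm.counts[i, j] == sum(
                    1 for x, y in zip(true, pred) if x == t and y == p
                )

    def test_benign_subpatterns_merge_into_benign(self):
        cm = ct.build_confusion(
            ["benign_gray", "benign_control_like"], ["benign_control_like", "gray"]
        )
        b = cm.class_order.index("benign")
        assert cm.counts[b].sum() == 2
        assert cm.counts[b, b] == 1
        assert merge_benign("benign_gray") == "benign"
        assert merge_benign("control") == "control"

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            ct.build_confusion(["white"], ["mystery"])

    def test_rows_stochastic(self):
        rng = np.random.default_rng(18)
        cm = ct.build_confusion(
            list(rng.choice(("white", "gray"), 30)),
            list(rng.choice(("white", "gray"), 30)),
        )
        occupied = cm.counts.sum(axis=1) > 0
        np.testing.assert_allclose(cm.proportions[occupied].sum(axis=1), 1.0)


class TestRates:
    def test_identity_matrix_rates_100(self):
        cm = ct.ConfusionMatrix.from_proportions(
            ct.DEFAULT_CLASS_ORDER, np.eye(8)
        )
        assert ct.sensitivity_from_confusion(cm) == 100
        assert ct.specificity_from_confusion(cm) == 100

    def test_fully_misassigned_nondiseased_rate_0(self):
        props = np.eye(8)
        for c in ("benign", "control"):
            i = ct.DEFAULT_CLASS_ORDER.index(c)
            props[i] = 0.0
            props[i, 0] = 1.0  # everything lands in the white column
        cm = ct.ConfusionMatrix.from_proportions(ct.DEFAULT_CLASS_ORDER, props)
        assert ct.specificity_from_confusion(cm) == 0
        assert ct.sensitivity_from_confusion(cm) == 100

    def test_reference_tables_sensitivity_values(self):
        expected = {"t1": 98, "t2": 98, "t3": 98, "t4": 82}
        for name, want in expected.items():
            cm = ct.load_printed_table(name)
            assert ct.sensitivity_from_confusion(cm) == want

    def test_reference_table_specificity_textbook_definition(self):
        # the textbook row-mean true-negative rate over benign+control rows
        cm = ct.load_printed_table("t1")
        assert ct.specificity_from_confusion(cm) == 41

    def test_reference_table_rows_near_stochastic(self):
        for name in ("t1", "t2", "t3", "t4"):
            cm = ct.load_printed_table(name)
            np.testing.assert_allclose(cm.proportions.sum(axis=1), 1.0, atol=0.005)

    def test_empty_partition_rejected(self):
        cm = ct.ConfusionMatrix.from_proportions(ct.DEFAULT_CLASS_ORDER, np.eye(8))
        with pytest.raises(ValueError):
            ct.sensitivity_from_confusion(cm, diseased_classes=())


class TestRunExperiment:
    def test_separated_data_diagonal_dominant(self):
        data = toy_set(12, seed=5)
        cm, summary = ct.run_experiment(
            data, SplitSpec(0.5, seed=2), ct.KnnConfig(3), class_order=("a", "b", "c")
        )
        assert summary["accuracy"] >= 0.95
        assert np.all(np.diag(cm.proportions) >= 0.9)

    def test_same_seed_reproducible(self):
        data = toy_set(10, seed=6)
        r1 = ct.run_experiment(data, SplitSpec(0.5, seed=9), class_order=("a", "b", "c"))
        r2 = ct.run_experiment(data, SplitSpec(0.5, seed=9), class_order=("a", "b", "c"))
        np.testing.assert_array_equal(r1[0].counts, r2[0].counts)
        assert r1[1] == r2[1]

    def test_resubstitution_k1_identity(self):
        data = toy_set(8, seed=7)
        norm = ct.fit_normalization(data)
        z = ct.LabeledPatternSet(
            ct.apply_normalization(norm, data.to_matrix()), data.labels,
            data.class_vocabulary,
        )
        preds = [ct.knn_classify(v, z, ct.KnnConfig(1)) for v in z.to_matrix()]
        cm = ct.build_confusion(data.labels, preds, ("a", "b", "c"))
        np.testing.assert_allclose(cm.proportions, np.eye(3))

    def test_leave_one_out_issues_n_predictions(self):
        data = toy_set(4, seed=8)
        cm, summary = ct.run_experiment(
            data, SplitSpec(leave_one_out=True), class_order=("a", "b", "c")
        )
        assert summary["n_test"] == len(data)
        assert cm.counts.sum() == len(data)

    def test_test_order_does_not_change_predictions(self):
        data = toy_set(10, seed=10)
        train, test = split_train_test(data, SplitSpec(0.5, seed=0))
        norm = ct.fit_normalization(train)
        z = ct.LabeledPatternSet(
            ct.apply_normalization(norm, train.to_matrix()), train.labels,
            train.class_vocabulary,
        )
        fwd = [
            ct.knn_classify(ct.apply_normalization(norm, v), z, ct.KnnConfig(3))
            for v in test.to_matrix()
        ]
        rev = [
            ct.knn_classify(ct.apply_normalization(norm, v), z, ct.KnnConfig(3))
            for v in test.to_matrix()[::-1]
        ]
        assert fwd == rev[::-1]


class TestSeparabilityExperiment:
    def test_three_group_recovery(self):
        data = toy_set(14, classes=("u", "v", "w"), seed=11)
        cm = run_separability_experiment(
            data,
            groups={"u": ["u"], "v": ["v"], "w": ["w"]},
            spec=SplitSpec(0.5, seed=0),
            repeats=10,
        )
        assert tuple(cm.class_order) == ("u", "v", "w")
        np.testing.assert_allclose(np.diag(cm.proportions), 1.0)
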