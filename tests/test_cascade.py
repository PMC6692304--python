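"""Cascade fusion rule, sensitivity evaluation and the sensitivity bounds."""

import numpy as np
import pytest

import ordcascades as oc
from conftest import random_rate_table

from test_rates import one_d_dataset


class ThresholdModel:
    """Stub binary model: predicts `first` below the threshold, else `second`."""

    def __init__(self, threshold, first, second):
        self.threshold = threshold
        self.first = first
        self.second = second

    def predict(self, X):
        return np.where(np.asarray(X)[:, 0] < self.threshold, self.first, self.second)


def threshold_cascade_models(order, thresholds):
    return {
        (order.labels[k], order.labels[k + 1]): ThresholdModel(
            thresholds[k], order.labels[k], order.labels[k + 1]
        )
        for k in range(len(order) - 1)
    }


class TestPredictCascade:
    def test_matches_sequential_truth_table_on_1d_grid(self):
        """Four 1-D threshold models; the cascade output is checked against an
        independent simulation of the fusion rule over the binary decision
        pattern of every sample."""
        order = oc.ClassOrder(("y1", "y2", "y3", "y4"))
        thresholds = [1.5, 2.5, 3.5]
        models = threshold_cascade_models(order, thresholds)
        for x in np.arange(0.0, 5.0, 0.1):
            # oracle: first base classifier deciding for its first class wins
            decisions = [x < t for t in thresholds]
            expected = order.labels[-1]
            for k, stop in enumerate(decisions):
                if stop:
                    expected = order.labels[k]
                    break
            assert oc.predict_cascade([x], order, models) == expected

    def test_sample_between_second_and_third_threshold_gets_second_label(self):
        order = oc.ClassOrder(("y1", "y2", "y3", "y4"))
        models = threshold_cascade_models(order, [1.5, 2.5, 3.5])
        assert oc.predict_cascade([2.2], order, models) == "y2"

    def test_all_pass_on_yields_last_label(self):
        order = oc.ClassOrder(("y1", "y2", "y3"))
        models = threshold_cascade_models(order, [-1.0, -1.0])
        assert oc.predict_cascade([0.0], order, models) == "y3"

    def test_two_class_cascade_equals_binary_model(self):
        order = oc.ClassOrder(("a", "b"))
        model = ThresholdModel(1.0, "a", "b")
        for x in (-3.0, 0.5, 2.0):
            assert oc.predict_cascade([x], order, {("a", "b"): model}) == model.predict([[x]])[0]

    def test_missing_pair_model_is_named(self):
        order = oc.ClassOrder(("a", "b", "c"))
        models = {("a", "b"): ThresholdModel(0.0, "a", "b")}
        with pytest.raises(KeyError, match="'b', 'c'"):
            oc.predict_cascade([5.0], order, models)


class TestBoundForOrder:
    def test_perfect_table_bounds_everything_at_one(self, make_random_table):
        from conftest import constant_rate_table

        table = constant_rate_table(4, 1.0)
        for perm in [("a", "b", "c", "d"), ("d", "b", "a", "c")]:
            assert oc.bound_for_order(table, oc.ClassOrder(perm)).overall_bound == 1.0

    def test_matches_flat_enumeration_oracle(self):
        """Overall bound equals the minimum over the flat list of all
        first-class and chain pass-on constraint terms."""
        rng = np.random.default_rng(11)
        for trial in range(10):
            table = random_rate_table(rng, 5)
            perm = tuple(np.array(table.labels)[rng.permutation(5)])
            order = oc.ClassOrder(perm)
            idx = [table.index(l) for l in perm]
            terms = []
            for i in range(5):
                if i < 4:
                    terms.append(table.fc[idx[i], idx[i + 1]])
                for k in range(i):
                    terms.append(table.sc[idx[k], idx[k + 1], idx[i]])
            report = oc.bound_for_order(table, order)
            assert report.overall_bound == pytest.approx(min(terms), abs=0)

    def test_edge_positions(self, make_random_table):
        rng = np.random.default_rng(3)
        table = make_random_table(rng, 3)
        report = oc.bound_for_order(table, oc.ClassOrder(table.labels))
        assert report.chain_bounds[0] is None  # no classifier precedes position 1
        assert report.fc_bounds[-1] is None  # no classifier has the last label first
        assert report.overall_bound == min(report.class_bounds)

    def test_unknown_label_rejected(self, make_random_table):
        table = make_random_table(np.random.default_rng(0), 3)
        with pytest.raises(ValueError, match="unknown"):
            oc.bound_for_order(table, oc.ClassOrder(("a", "zz")))


class TestEvaluateCascade:
    def test_two_class_order_reproduces_base_classifier_cv_rates(self):
        ds = one_d_dataset({"a": 0.0, "b": 1.0}, n=12, sd=0.6, seed=7)
        folds = oc.make_folds(ds, repeats=2, folds=3, seed=8)
        table = oc.train_pairwise_table(ds, folds)
        report = oc.evaluate_cascade(ds, oc.ClassOrder(("a", "b")), folds, table)
        assert report.sensitivity("a") == pytest.approx(table.fc_rate("a", "b"), abs=0)
        assert report.sensitivity("b") == pytest.approx(table.sc_rate("a", "b", "b"), abs=0)

    def test_swapped_order_matches_per_sample_simulation(self):
        """Class-wise sensitivities under a deliberately swapped order equal
        an independent per-split, per-sample sequential evaluation with
        freshly fitted base classifiers."""
        from sklearn.svm import SVC

        ds = one_d_dataset({"a": 0.0, "b": 3.0, "c": 6.0}, n=12, sd=1.0, seed=9)
        folds = oc.make_folds(ds, repeats=2, folds=3, seed=10)
        table = oc.train_pairwise_table(ds, folds)
        order = oc.ClassOrder(("b", "c", "a"))
        report = oc.evaluate_cascade(ds, order, folds, table)

        y, X = ds.label_indices, ds.features
        idx = {l: ds.label_index(l) for l in "abc"}
        sens = {l: [] for l in "bca"}
        for rep, fold, tr, te in folds.splits():
            models = {}
            for first, second in (("b", "c"), ("c", "a")):
                keep = np.isin(y[tr], [idx[first], idx[second]])
                models[(first, second)] = SVC(kernel="linear", C=1.0).fit(X[tr][keep], y[tr][keep])
            for label in "bca":
                correct = 0
                members = te[y[te] == idx[label]]
                for s in members:
                    out = "a"
                    for first, second in (("b", "c"), ("c", "a")):
                        if models[(first, second)].predict(X[[s]])[0] == idx[first]:
                            out = first
                            break
                    correct += out == label
                sens[label].append(correct / len(members))
        for label in "bca":
            assert report.sensitivity(label) == pytest.approx(float(np.mean(sens[label])), abs=1e-12)

    def test_unreachable_class_has_zero_sensitivity(self):
        """Under order (b, a, c) the first classifier claims class c's region
        for b, so c is never reached and p* collapses to zero."""
        ds = one_d_dataset({"a": 0.0, "b": 5.0, "c": 10.0}, n=12, sd=0.3, seed=11)
        folds = oc.make_folds(ds, repeats=2, folds=3, seed=12)
        table = oc.train_pairwise_table(ds, folds)
        report = oc.evaluate_cascade(ds, oc.ClassOrder(("b", "a", "c")), folds, table)
        assert report.sensitivity("c") == 0.0
        assert report.min_sensitivity == 0.0

    def test_partial_cascade_ignores_foreign_classes(self):
        ds = one_d_dataset({"a": 0.0, "b": 5.0, "c": 10.0}, n=12, sd=0.3, seed=13)
        folds = oc.make_folds(ds, repeats=2, folds=3, seed=14)
        table = oc.train_pairwise_table(ds, folds)
        report = oc.evaluate_cascade(ds, oc.ClassOrder(("a", "b")), folds, table)
        assert set(report.to_dict()["class_sensitivities"]) == {"a", "b"}
        assert report.min_sensitivity == pytest.approx(1.0)


class TestBoundDominance:
    def test_sensitivities_never_exceed_bounds_on_random_orders(self, six_class):
        """Empirical form of the sensitivity-bound theorem: with shared folds
        and shared base models, every class-wise sensitivity is bounded by
        its per-position bound, hence p* by the overall bound."""
        dataset, folds, table = six_class
        rng = np.random.default_rng(21)
        labels = np.array(dataset.label_space)
        for _ in range(100):
            order = oc.ClassOrder(tuple(labels[rng.permutation(6)]))
            report = oc.evaluate_cascade(dataset, order, folds, table)
            for sens, bound in zip(report.class_sensitivities, report.bounds.class_bounds):
                assert sens <= bound + 1e-9
            assert report.min_sensitivity <= report.bounds.overall_bound + 1e-9

    def test_prediction_fractions_partition(self, six_class):
        """Cascade predictions stay inside the order's labels and per-class
        prediction fractions sum to one on every evaluation set."""
        dataset, folds, table = six_class
        order = oc.ClassOrder(dataset.label_space[::-1])
        idx = [table.index(l) for l in order.labels]
        from ordcascades.cascade import _cascade_labels

        for split in table.splits[:10]:
            out = _cascade_labels(split, idx)
            assert set(out) <= set(idx)
            fractions = [np.mean(out == i) for i in idx]
            assert sum(fractions) == pytest.approx(1.0)
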