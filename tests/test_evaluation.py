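"""Splits, SMOTE, Youden thresholding, metrics, and leakage hygiene."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from survimage.evaluation import (
    fit_split_artifacts,
    make_splits,
    smote_oversample,
    thresholded_metrics,
    youden_threshold,
)
from survimage.cohort_data import ExpressionMatrix, LabeledCohort


def sweep_oracle(scores, labels):
    """Naive exhaustive midpoint sweep (rule: score > t -> positive)."""
    uniq = sorted(set(scores))
    candidates = [max(uniq[0] / 2, 0.0)]
    candidates += [(a + b) / 2 for a, b in zip(uniq, uniq[1:])]
    candidates += [uniq[-1]]
    n_pos = sum(1 for y in labels if y == 1)
    n_neg = len(labels) - n_pos
    best_t, best_j = None, -float("inf")
    for t in candidates:
        tp = sum(1 for s, y in zip(scores, labels) if s > t and y == 1)
        fp = sum(1 for s, y in zip(scores, labels) if s > t and y == 0)
        j = tp / n_pos - fp / n_neg
        if j > best_j + 1e-12:
            best_j, best_t = j, t
    return best_t, best_j


class TestMakeSplits:
    def test_test_size_is_ceil_fraction(self, rng):
        labels = {f"s{i}": int(i < 3) for i in range(10)}
        plan = make_splits(list(labels), labels, n_repeats=3, base_seed=0)
        for r in plan.repeats:
            assert len(r.test_ids) == 2
            assert set(r.train_ids) | set(r.test_ids) == set(labels)
            assert set(r.train_ids).isdisjoint(r.test_ids)

    def test_471_samples_split_95_376(self):
        labels = {f"s{i}": int(i < 123) for i in range(471)}
        plan = make_splits(list(labels), labels, n_repeats=1, base_seed=0)
        assert len(plan.repeats[0].test_ids) == math.ceil(0.2 * 471) == 95
        assert len(plan.repeats[0].train_ids) == 376

    def test_deterministic_per_seed(self):
        labels = {f"s{i}": i % 2 for i in range(20)}
        p1 = make_splits(list(labels), labels, n_repeats=4, base_seed=9)
        p2 = make_splits(list(labels), labels, n_repeats=4, base_seed=9)
        assert p1.repeats == p2.repeats

    def test_stratification_keeps_both_classes(self):
        labels = {f"s{i}": int(i < 5) for i in range(25)}
        plan = make_splits(list(labels), labels, n_repeats=10, base_seed=0)
        for r in plan.repeats:
            assert len({labels[s] for s in r.train_ids}) == 2
            assert len({labels[s] for s in r.test_ids}) == 2

    def test_single_class_rejected(self):
        labels = {f"s{i}": 1 for i in range(10)}
        with pytest.raises(ValueError, match="both classes"):
            make_splits(list(labels), labels, n_repeats=1)


class TestSmote:
    def test_balanced_input_unchanged(self, rng):
        X = rng.random((8, 4))
        y = np.array([0, 1] * 4)
        Xo, yo = smote_oversample(X, y, seed=0)
        np.testing.assert_array_equal(Xo, X)
        np.testing.assert_array_equal(yo, y)

    def test_exact_balance_and_convexity(self, rng):
        X = np.vstack([rng.random((3, 5)) + 5, rng.random((9, 5))])
        y = np.array([1] * 3 + [0] * 9)
        Xo, yo = smote_oversample(X, y, seed=1)
        assert (yo == 1).sum() == (yo == 0).sum() == 9
        np.testing.assert_array_equal(Xo[:12], X)  # originals preserved
        minority = X[:3]
        for row in Xo[12:]:
            # each synthetic point lies on a segment between two minority originals
            on_segment = False
            for i in range(3):
                for j in range(3):
                    if i == j:
                        continue
                    d = minority[j] - minority[i]
                    denom = d @ d
                    if denom == 0:
                        continue
                    u = (row - minority[i]) @ d / denom
                    if -1e-9 <= u <= 1 + 1e-9 and np.allclose(
                        row, minority[i] + u * d, atol=1e-9
                    ):
                        on_segment = True
            assert on_segment

    def test_minority_of_one_rejected(self, rng):
        X = rng.random((5, 3))
        y = np.array([1, 0, 0, 0, 0])
        with pytest.raises(ValueError, match="minority"):
            smote_oversample(X, y, seed=0)


class TestYoudenThreshold:
    def test_perfect_separation(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [0, 0, 1, 1]
        t, j = youden_threshold(scores, labels)
        assert j == 1.0 and 0.2 < t <= 0.8

    def test_toy_matches_exhaustive_oracle(self):
        scores = [0.1, 0.4, 0.35, 0.8]
        labels = [0, 0, 1, 1]
        assert youden_threshold(scores, labels) == sweep_oracle(scores, labels)

    def test_random_scores_give_small_j(self, rng):
        n = 2000
        labels = rng.integers(0, 2, n)
        scores = rng.random(n)
        _, j = youden_threshold(scores, labels)
        assert j < 0.1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            youden_threshold([0.1, 0.9], [1, 1])

    @settings(max_examples=100, deadline=None)
    @given(st.data())
    def test_equals_oracle_on_random_instances(self, data):
        n = data.draw(st.integers(4, 50))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        scores = np.round(rng.random(n), 3)
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            labels[0], labels[1] = 0, 1
        t, j = youden_threshold(scores, labels)
        t_o, j_o = sweep_oracle(scores.tolist(), labels.tolist())
        assert j == pytest.approx(j_o, abs=1e-12)
        assert t == pytest.approx(t_o, abs=1e-12)


class TestThresholdedMetrics:
    def test_worked_confusion_table(self):
        # TP=3, FP=1, TN=4, FN=2 -> acc 0.7, prec 0.75, rec 0.6, F1 2/3
        scores = [0.9] * 3 + [0.9] + [0.1] * 4 + [0.1] * 2
        labels = [1] * 3 + [0] + [0] * 4 + [1] * 2
        m, c = thresholded_metrics(scores, labels, 0.5)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 1, 4, 2)
        assert m.accuracy == pytest.approx(0.7)
        assert m.precision == pytest.approx(0.75)
        assert m.recall == pytest.approx(0.6)
        assert m.f1 == pytest.approx(2 / 3)

    def test_all_correct(self):
        m, c = thresholded_metrics([0.9, 0.1], [1, 0], 0.5)
        assert m.accuracy == 1.0 and m.f1 == 1.0

    def test_no_predicted_positives_yields_zero_precision(self):
        m, c = thresholded_metrics([0.1, 0.2], [1, 0], 0.5)
        assert m.precision == 0.0 and m.recall == 0.0 and m.f1 == 0.0

    def test_identities_on_random_tables(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 40))
            scores = rng.random(n)
            labels = rng.integers(0, 2, n)
            t = float(rng.random())
            m, c = thresholded_metrics(scores, labels, t)
            assert c.total == n
            tp, fp, tn, fn = c.tp, c.fp, c.tn, c.fn
            assert m.accuracy == pytest.approx((tp + tn) / n)
            assert m.precision == pytest.approx(tp / (tp + fp) if tp + fp else 0.0)
            assert m.recall == pytest.approx(tp / (tp + fn) if tp + fn else 0.0)
            pr = m.precision + m.recall
            assert m.f1 == pytest.approx(
                2 * m.precision * m.recall / pr if pr else 0.0
            )
            assert 0 <= m.threshold <= 1


class TestLeakageHygiene:
    def test_test_fold_expression_never_touches_fitted_artifacts(
        self, small_cohort, small_annotation, rng
    ):
        """Replacing test-fold expression with noise leaves every fitted
        artifact identical in default (leak-free) mode."""
        cohort, _ = small_cohort
        assets = small_annotation.assets()
        ids = cohort.labeled_sample_ids
        plan = make_splits(ids, cohort.labels, n_repeats=1, base_seed=0)
        repeat = plan.repeats[0]

        noisy_values = cohort.expression.values.copy()
        test_cols = [cohort.expression.sample_ids.index(s) for s in repeat.test_ids]
        noisy_values[:, test_cols] = rng.normal(size=(len(noisy_values), len(test_cols)))
        noisy_cohort = LabeledCohort(
            ExpressionMatrix(
                noisy_values,
                cohort.expression.gene_ids,
                cohort.expression.sample_ids,
            ),
            cohort.clinical,
            cohort.labels,
            cohort.excluded,
        )
        # the unsupervised variance filter intentionally sees all samples, so
        # pin the candidate set and probe the supervised/fitted steps
        kwargs = dict(k=20, candidate_genes=cohort.expression.gene_ids, seed=0)
        a1 = fit_split_artifacts(cohort, assets, repeat.train_ids, **kwargs)
        a2 = fit_split_artifacts(noisy_cohort, assets, repeat.train_ids, **kwargs)
        assert a1.selected_genes == a2.selected_genes
        assert a1.fingerprint == a2.fingerprint
        for name in a1.layouts:
            assert a1.layouts[name].ordered_genes == a2.layouts[name].ordered_genes
            np.testing.assert_array_equal(
                a1.layouts[name].scaler.x_min, a2.layouts[name].scaler.x_min
            )
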