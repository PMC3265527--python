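import numpy as np
import pytest

from mirevo.evaluate import (
    ConfusionCounts,
    composite_metrics,
    correlation_ranking,
    cross_validate,
    cumulative_feature_ranking,
    fscore,
    indirect_metrics,
)


class TestCompositeMetrics:
    def test_worked_example(self):
        c = ConfusionCounts(tp_ml=8, fp_ml=1, tn_ml=2, fn_ml=1, tn_ab=3, fn_ab=1)
        rep = composite_metrics(c)
        assert rep.accuracy == pytest.approx(13 / 16)
        assert rep.specificity == pytest.approx(5 / 6)
        assert rep.sensitivity == pytest.approx(8 / 10)

    def test_perfect_prediction(self):
        rep = composite_metrics(ConfusionCounts(tp_ml=5, tn_ml=4, tn_ab=3))
        assert (rep.accuracy, rep.specificity, rep.sensitivity) == (1.0, 1.0, 1.0)

    def test_zero_tp_with_ab_misses(self):
        rep = composite_metrics(ConfusionCounts(fn_ab=4, tn_ml=1))
        assert rep.sensitivity == 0.0

    def test_zero_denominator_reported_undefined(self):
        rep = composite_metrics(ConfusionCounts())
        assert rep.accuracy is None
        assert rep.sensitivity is None

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp_ml=-1)

    def test_reduces_to_single_stage_metrics(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, size=4))
            rep = composite_metrics(
                ConfusionCounts(tp_ml=tp, fp_ml=fp, tn_ml=tn, fn_ml=fn)
            )
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))
            assert rep.specificity == pytest.approx(tn / (fp + tn))
            assert rep.sensitivity == pytest.approx(tp / (tp + fn))

    def test_monotone_in_ab_counts(self):
        base = dict(tp_ml=5, fp_ml=3, tn_ml=4, fn_ml=2)
        q0 = composite_metrics(ConfusionCounts(**base, tn_ab=0, fn_ab=2)).accuracy
        q1 = composite_metrics(ConfusionCounts(**base, tn_ab=5, fn_ab=2)).accuracy
        q2 = composite_metrics(ConfusionCounts(**base, tn_ab=0, fn_ab=9)).accuracy
        assert q1 > q0 > q2


class TestIndirectMetrics:
    def test_exact_prediction(self):
        ss = {"a", "b", "c"}
        assert indirect_metrics(ss, ss | {"d"}, ss) == (1.0, 1.0)

    def test_disjoint_prediction(self):
        assert indirect_metrics({"x"}, {"x", "a", "b"}, {"a", "b"}) == (0.0, 0.0)

    def test_partial_overlap(self):
        ss = {f"s{i}" for i in range(10)}
        predicted = {f"s{i}" for i in range(5)} | {f"p{i}" for i in range(15)}
        evaluated = ss | predicted
        assert indirect_metrics(predicted, evaluated, ss) == (0.5, 0.25)

    def test_ss_not_subset_rejected(self):
        with pytest.raises(ValueError):
            indirect_metrics({"a"}, {"a"}, {"a", "z"})

    def test_empty_sets_undefined(self):
        sens, prec = indirect_metrics(set(), {"a"}, set())
        assert sens is None and prec is None


class TestFscore:
    def test_worked_example(self):
        assert fscore([0, 4], [1, 1]) == pytest.approx(0.5)

    def test_identical_distributions_zero(self):
        assert fscore([1, 2, 3], [3, 2, 1]) == 0.0

    def test_equal_sigmas_undefined(self):
        assert fscore([0, 2], [5, 7]) is None

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            fscore([], [1.0])

    def test_invariance_to_label_swap_and_shift(self):
        rng = np.random.default_rng(0)
        p = rng.normal(0, 1, 30)
        n = rng.normal(2, 3, 30)
        a = fscore(p, n)
        assert fscore(n, p) == pytest.approx(a)
        assert fscore(p + 10, n + 10) == pytest.approx(a)

    def test_standard_variant_uses_sigma_sum(self):
        # mu 2 vs 1; sigma 2 vs 1: printed form gives 1/|2-1|, standard 1/(2+1)
        assert fscore([0, 4], [0, 2]) == pytest.approx(1.0)
        assert fscore([0, 4], [0, 2], standard=True) == pytest.approx(1 / 3)


class TestCorrelationRanking:
    def test_independent_feature_wins(self):
        rng = np.random.default_rng(1)
        f1 = rng.normal(size=300)
        f2 = f1 + rng.normal(scale=0.05, size=300)  # strongly tied to f1
        f3 = rng.normal(size=300)  # independent
        sums = correlation_ranking(np.column_stack([f1, f2, f3]))
        assert np.argmin(sums) == 2

    def test_two_features_symmetric(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(50, 2))
        sums = correlation_ranking(X)
        assert sums[0] == sums[1] == 1.0

    def test_duplicated_feature_ranks_last(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=200)
        b = rng.normal(size=200)
        c = rng.normal(size=200)
        X = np.column_stack([a, a.copy(), b, c])
        sums = correlation_ranking(X)
        assert set(np.argsort(sums)[-2:]) == {0, 1}

    def test_too_small_input_rejected(self):
        with pytest.raises(ValueError):
            correlation_ranking(np.ones((2, 3)))


class TestCumulativeRanking:
    def test_agreeing_rankings(self):
        final, fs, cr = cumulative_feature_ranking([0.9, 0.5, 0.1], [3.0, 6.0, 9.0])
        assert final.tolist() == [1, 2, 3]
        assert fs.tolist() == [1, 2, 3]
        assert cr.tolist() == [1, 2, 3]

    def test_exchangeable_features_share_rank(self):
        final, _, _ = cumulative_feature_ranking([0.5, 0.5], [2.0, 2.0])
        assert final.tolist() == [1, 1]

    def test_four_feature_hand_computation(self):
        f_scores = [0.5, 0.1, 0.4, 0.2]
        corr_sums = [10.0, 4.0, 6.0, 8.0]
        # F-score ranks: [1, 4, 2, 3]; correlation ranks: [4, 1, 2, 3]
        # totals: [5, 5, 4, 6] -> final competition ranks [2, 2, 1, 4]
        final, fs, cr = cumulative_feature_ranking(f_scores, corr_sums)
        assert fs.tolist() == [1, 4, 2, 3]
        assert cr.tolist() == [4, 1, 2, 3]
        assert final.tolist() == [2, 2, 1, 4]

    def test_undefined_fscore_ranks_last(self):
        final, fs, _ = cumulative_feature_ranking([0.5, None, 0.2], [3.0, 3.0, 3.0])
        assert fs.tolist() == [1, 3, 2]


class FakeRecord:
    def __init__(self, mirna_id, value, label):
        self.mirna_id = mirna_id
        self.value = value
        self.label = label


def threshold_scorer(train, test):
    """Accuracy of a midpoint-threshold classifier fitted on the fold."""
    mids = []
    for lab in (0, 1):
        mids.append(np.mean([r.value for r in train if r.label == lab]))
    cut = np.mean(mids)
    correct = sum((r.value > cut) == bool(r.label) for r in test)
    return correct / len(test)


def make_cv_records(rng, n_mirnas=30, per_mirna=6, sep=2.0):
    records = []
    for i in range(n_mirnas):
        for k in range(per_mirna):
            label = k % 2
            records.append(
                FakeRecord(f"mir-{i}", rng.normal(label * sep, 1.0), label)
            )
    return records


class TestCrossValidate:
    def test_constant_metric_zero_ci(self, rng):
        records = make_cv_records(rng)
        mean, half = cross_validate(
            records, lambda tr, te: 0.75, k_folds=5, runs=4, rng_seed=0
        )
        assert mean == 0.75 and half == 0.0

    def test_same_seed_reproducible(self, rng):
        records = make_cv_records(rng)
        a = cross_validate(records, threshold_scorer, k_folds=5, runs=3, rng_seed=9)
        b = cross_validate(records, threshold_scorer, k_folds=5, runs=3, rng_seed=9)
        assert a == b

    def test_folds_are_mirna_disjoint(self, rng):
        records = make_cv_records(rng)
        seen = []

        def spy(train, test):
            tr = {r.mirna_id for r in train}
            te = {r.mirna_id for r in test}
            assert tr.isdisjoint(te)
            seen.extend(te)
            return 1.0

        cross_validate(records, spy, k_folds=5, runs=1, rng_seed=0)
        # folds partition the miRNAs
        assert sorted(seen) == sorted({r.mirna_id for r in records})

    def test_too_few_mirnas_rejected(self, rng):
        records = make_cv_records(rng, n_mirnas=4)
        with pytest.raises(ValueError, match="smaller k"):
            cross_validate(records, threshold_scorer, k_folds=10)

    def test_mean_accuracy_near_known_overlap(self, rng):
        # centers 0 and 2, sigma 1: Bayes accuracy = Phi(1) ~ 0.841
        records = make_cv_records(rng, n_mirnas=40, per_mirna=10, sep=2.0)
        mean, half = cross_validate(records, threshold_scorer, k_folds=8, runs=3,
                                    rng_seed=4)
        assert abs(mean - 0.841) < 0.05
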