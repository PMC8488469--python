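import itertools

import numpy as np
import pytest
from sklearn.metrics import matthews_corrcoef, roc_auc_score

from plantppi.evaluation import (
    Confusion,
    candidate_pair_count,
    confusion,
    kfold_split,
    metrics,
    negative_candidate_count,
    roc_auc,
    run_cv,
    sample_negatives,
)
from plantppi.io_formats import InteractionPair


def rank_auc(y, scores):
    """Brute-force rank statistic: P(score+ > score-) + 0.5 P(tie)."""
    pos = [s for s, l in zip(scores, y) if l == 1]
    neg = [s for s, l in zip(scores, y) if l == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestConfusion:
    def test_correct_predictions(self):
        c = confusion([1, 0], [0.9, 0.1])
        assert (c.tp, c.fp, c.tn, c.fn) == (1, 0, 1, 0)

    def test_inverted_predictions(self):
        c = confusion([1, 0], [0.1, 0.9])
        assert (c.fn, c.fp) == (1, 1)

    def test_tie_at_threshold_counts_positive(self):
        c = confusion([1, 0], [0.5, 0.5])
        assert (c.tp, c.fp) == (1, 1)

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            confusion([], [])

    def test_total_invariant(self, rng):
        y = rng.integers(0, 2, size=50)
        s = rng.random(50)
        assert confusion(y, s).total == 50


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(Confusion(tp=5, fp=0, tn=5, fn=0))
        assert (m.acc, m.pr, m.sens, m.spec, m.mcc) == (1, 1, 1, 1, 1)

    def test_fully_inverted_classifier(self):
        m = metrics(Confusion(tp=0, fp=5, tn=0, fn=5))
        assert m.acc == 0
        assert m.mcc == -1

    def test_hand_evaluated_mixed_table(self):
        m = metrics(Confusion(tp=3, fp=1, tn=2, fn=2))
        assert m.acc == pytest.approx(5 / 8)
        assert m.mcc == pytest.approx(4 / np.sqrt(240))

    def test_zero_denominators_report_zero_with_warning(self):
        with pytest.warns(UserWarning):
            m = metrics(Confusion(tp=0, fp=0, tn=4, fn=0))
        assert m.pr == 0
        assert m.mcc == 0

    def test_accuracy_identity_with_sens_spec(self):
        """Acc == (Sens*P + Spec*N)/(P+N) for every non-degenerate table."""
        import warnings

        for tp, fp, tn, fn in itertools.product(range(4), repeat=4):
            if (tp + fn) == 0 or (fp + tn) == 0:
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics(Confusion(tp, fp, tn, fn))
            P, N = tp + fn, fp + tn
            assert m.acc == pytest.approx((m.sens * P + m.spec * N) / (P + N))

    def test_mcc_invariant_under_class_and_prediction_flip(self):
        import warnings

        for tp, fp, tn, fn in [(3, 1, 2, 2), (5, 0, 1, 4), (2, 2, 2, 2)]:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m1 = metrics(Confusion(tp, fp, tn, fn))
                m2 = metrics(Confusion(tn, fn, tp, fp))
            assert m1.mcc == pytest.approx(m2.mcc)

    def test_mcc_matches_sklearn_on_realised_vectors(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, size=30)
            pred = rng.integers(0, 2, size=30)
            if len(set(y)) < 2 or len(set(pred)) < 2:
                continue
            c = confusion(y, pred.astype(float), threshold=0.5)
            assert metrics(c).mcc == pytest.approx(matthews_corrcoef(y, pred))


class TestRocAuc:
    def test_perfect_separation(self):
        _, auc = roc_auc([1, 1, 0, 0], [0.9, 0.8, 0.2, 0.1])
        assert auc == 1.0

    def test_all_ties_give_half(self):
        _, auc = roc_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == 0.5

    def test_worked_example_matches_pair_counting(self):
        # pairs: (0.9,0.6) correct, (0.9,0.2) correct, (0.4,0.6) wrong,
        # (0.4,0.2) correct -> 3/4
        y, s = [1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2]
        _, auc = roc_auc(y, s)
        assert auc == pytest.approx(0.75)
        assert auc == pytest.approx(rank_auc(y, s))

    def test_single_class_errors(self):
        with pytest.raises(ValueError):
            roc_auc([1, 1], [0.2, 0.3])

    def test_curve_endpoints(self, rng):
        y = rng.integers(0, 2, size=40)
        y[:2] = [0, 1]
        points, _ = roc_auc(y, rng.random(40))
        assert points[0][:2] == (0.0, 0.0)
        assert points[-1][:2] == (1.0, 1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_trapezoid_equals_rank_statistic(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        y = rng.integers(0, 2, size=n)
        y[:2] = [0, 1]
        scores = np.round(rng.random(n), 2)  # rounding forces ties
        _, auc = roc_auc(y, scores)
        assert auc == pytest.approx(rank_auc(y, scores), abs=1e-12)
        assert auc == pytest.approx(roc_auc_score(y, scores), abs=1e-12)


def _pairs(n_pos, n_neg):
    pairs = [InteractionPair(f"a{i}", f"b{i}", 1) for i in range(n_pos)]
    pairs += [InteractionPair(f"c{i}", f"d{i}", 0) for i in range(n_neg)]
    return pairs


class TestKfoldSplit:
    def test_ten_pairs_five_folds_of_two(self):
        folds = kfold_split(_pairs(5, 5), k=5, seed=0)
        assert sorted(len(f) for f in folds) == [2] * 5

    def test_partition_law(self):
        pairs = _pairs(13, 11)
        folds = kfold_split(pairs, k=5, seed=1)
        combined = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(combined, np.arange(24))

    def test_stratification_bound(self):
        pairs = _pairs(21, 14)
        folds = kfold_split(pairs, k=5, seed=2, stratified=True)
        labels = np.array([p.label for p in pairs])
        for fold in folds:
            n_pos = labels[fold].sum()
            expected = len(fold) * 21 / 35
            assert abs(n_pos - expected) <= 1

    def test_same_seed_identical(self):
        pairs = _pairs(10, 10)
        f1 = kfold_split(pairs, k=4, seed=9)
        f2 = kfold_split(pairs, k=4, seed=9)
        for a, b in zip(f1, f2):
            np.testing.assert_array_equal(a, b)

    def test_k_below_two_errors(self):
        with pytest.raises(ValueError):
            kfold_split(_pairs(3, 3), k=1)


class TestBipartiteArithmetic:
    def test_ordered_candidate_space(self):
        assert candidate_pair_count(3) == 9
        assert candidate_pair_count(3, ordered=False) == 3

    def test_negative_candidates(self):
        assert negative_candidate_count(3, 2) == 7


class TestSampleNegatives:
    def test_small_enumerated_space(self):
        ids = ["a", "b", "c"]
        positives = {("a", "b"), ("b", "c")}
        negs = sample_negatives(ids, positives, 7, seed=0)
        assert len(negs) == 7
        drawn = {(p.id_a, p.id_b) for p in negs}
        assert len(drawn) == 7
        assert drawn.isdisjoint(positives)

    def test_exhaustion_returns_all_remaining(self):
        ids = ["a", "b", "c"]
        positives = {("a", "b"), ("b", "c")}
        negs = sample_negatives(ids, positives, 7, seed=1)
        universe = {(x, y) for x in ids for y in ids}
        assert {(p.id_a, p.id_b) for p in negs} == universe - positives

    def test_over_request_errors_with_available_count(self):
        with pytest.raises(ValueError, match="7"):
            sample_negatives(["a", "b", "c"], {("a", "b"), ("b", "c")}, 8, seed=0)

    def test_never_emits_positive_or_duplicate(self):
        rng = np.random.default_rng(0)
        ids = [f"p{i}" for i in range(6)]
        for trial in range(10):
            k = int(rng.integers(0, 10))
            positives = {
                (ids[int(rng.integers(6))], ids[int(rng.integers(6))])
                for _ in range(k)
            }
            n = 36 - len(positives)
            negs = sample_negatives(ids, positives, n, seed=trial)
            drawn = [(p.id_a, p.id_b) for p in negs]
            assert len(set(drawn)) == len(drawn) == n
            assert set(drawn).isdisjoint(positives)
            assert all(p.label == 0 for p in negs)

    def test_unordered_excludes_self_pairs(self):
        negs = sample_negatives(["a", "b", "c"], set(), 3, seed=0, ordered=False)
        assert all(p.id_a != p.id_b for p in negs)

    def test_seeded_reproducibility(self):
        ids = [f"p{i}" for i in range(5)]
        n1 = sample_negatives(ids, set(), 10, seed=4)
        n2 = sample_negatives(ids, set(), 10, seed=4)
        assert n1 == n2


class TestRunCv:
    def test_report_shape_and_determinism(self, small_dataset):
        from plantppi.pipeline import RunConfig, run_features

        records, profiles, pairs = small_dataset
        table = run_features(records, profiles, RunConfig())
        feats = {pid: table.loc[pid].to_numpy() for pid in table.index}
        with pytest.warns(UserWarning, match="capping"):
            r1 = run_cv(feats, pairs, seed=5, folds=3)
            r2 = run_cv(feats, pairs, seed=5, folds=3)
        assert len(r1.folds) == 3
        assert r1.mean == r2.mean
        for m1, m2 in zip(r1.folds, r2.folds):
            assert m1 == m2

    def test_unresolvable_pair_ids_error(self):
        feats = {"a": np.zeros(400)}
        pairs = [InteractionPair("a", "zz", 1)] * 4
        with pytest.raises(ValueError, match="zz"):
            run_cv(feats, pairs, folds=2)

    def test_unknown_classifier_errors(self, small_dataset):
        from plantppi.pipeline import RunConfig, run_features

        records, profiles, pairs = small_dataset
        table = run_features(records, profiles, RunConfig())
        feats = {pid: table.loc[pid].to_numpy() for pid in table.index}
        with pytest.raises(ValueError, match="svm"):
            run_cv(feats, pairs, classifier="svm", svd_k=10, folds=2)
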