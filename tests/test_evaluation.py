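import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metakinase.evaluation import (
    MetricsReport,
    compute_metrics,
    kfold_cv,
    local_evaluate,
    pr_auc,
    roc_auc,
    sweep,
    threshold_metrics,
)


def brute_force_auc(scores, labels):
    """Pair counting over every positive x negative pair, ties as 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def brute_force_aupr(scores, labels):
    """Exhaustive sweep over every distinct score as threshold (step-wise area)."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n_pos = labels.sum()
    area, prev_recall = 0.0, 0.0
    for t in sorted(set(scores), reverse=True):
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        precision = tp / pred.sum()
        recall = tp / n_pos
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def random_score_sets(n_sets, max_n=50, seed=0, with_ties=True):
    rng = np.random.default_rng(seed)
    out = []
    while len(out) < n_sets:
        n = int(rng.integers(4, max_n + 1))
        labels = (rng.random(n) < 0.5).astype(int)
        if labels.min() == labels.max():
            continue
        if with_ties and rng.random() < 0.5:
            scores = rng.integers(0, 5, size=n).astype(float) / 4  # forces ties
        else:
            scores = rng.random(n)
        out.append((scores, labels))
    return out


class TestRocAuc:
    def test_perfect_and_inverted(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        assert roc_auc(scores, labels) == 1.0
        assert roc_auc(scores, 1 - labels) == 0.0

    def test_matches_pair_counting(self):
        for scores, labels in random_score_sets(100, seed=3):
            assert roc_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels), abs=1e-12
            )

    @settings(max_examples=30, derandomize=True)
    @given(
        shift=st.floats(-3, 3, allow_nan=False),
        scale=st.floats(0.01, 10, allow_nan=False),
    )
    def test_invariant_under_monotone_transform(self, shift, scale):
        scores, labels = random_score_sets(1, seed=8)[0]
        transformed = np.exp(scale * scores) + shift
        assert roc_auc(transformed, labels) == pytest.approx(
            roc_auc(scores, labels), abs=1e-12
        )

    def test_complement_identity_for_tie_free_scores(self):
        rng = np.random.default_rng(4)
        scores = rng.permutation(20) / 20.0
        labels = (rng.random(20) < 0.5).astype(int)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) + roc_auc(scores, 1 - labels) == pytest.approx(1.0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.4, 0.6], [1, 1])


class TestPrAuc:
    def test_perfect_separation(self):
        assert pr_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_single_top_ranked_positive(self):
        scores = np.linspace(1.0, 0.1, 10)
        labels = np.zeros(10, dtype=int)
        labels[0] = 1
        assert pr_auc(scores, labels) == 1.0

    def test_matches_exhaustive_threshold_sweep(self):
        for scores, labels in random_score_sets(100, seed=5):
            assert pr_auc(scores, labels) == pytest.approx(
                brute_force_aupr(scores, labels), abs=1e-12
            )

    def test_constant_scores_give_prevalence(self):
        labels = np.array([1, 0, 0, 0, 1, 0, 0, 0, 0, 0])
        assert pr_auc(np.full(10, 0.5), labels) == pytest.approx(0.2)

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            pr_auc([0.1, 0.2], [0, 0])


class TestThresholdMetrics:
    def test_all_correct(self):
        ba, p, r, f1, flag = threshold_metrics([0.9, 0.9, 0.1], [1, 1, 0])
        assert (ba, p, r, f1) == (1.0, 1.0, 1.0, 1.0)
        assert not flag

    def test_hand_computed_confusion_table(self):
        # TP=3 FP=1 FN=2 TN=4
        scores = [0.9, 0.8, 0.7, 0.6, 0.2, 0.3, 0.1, 0.15, 0.05, 0.25]
        labels = [1, 1, 1, 0, 1, 1, 0, 0, 0, 0]
        ba, p, r, f1, _ = threshold_metrics(scores, labels, threshold=0.5)
        assert p == pytest.approx(0.75)
        assert r == pytest.approx(0.6)
        assert ba == pytest.approx(0.7)
        assert f1 == pytest.approx(2 / 3, abs=1e-12)

    def test_no_predicted_positives_flagged(self):
        ba, p, r, f1, flag = threshold_metrics([0.1, 0.2], [1, 0])
        assert flag and p == 0.0 and r == 0.0

    def test_report_consistency(self):
        scores, labels = random_score_sets(1, seed=7)[0]
        rep = compute_metrics(scores, labels)
        spec = 2 * rep.ba - rep.recall  # ba = (recall + specificity) / 2
        assert 0.0 <= spec <= 1.0
        if rep.precision + rep.recall > 0:
            assert rep.f1 == pytest.approx(
                2 * rep.precision * rep.recall / (rep.precision + rep.recall)
            )


class TestKFold:
    @staticmethod
    def toy_pairs(n=40, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([1, 0] * (n // 2))
        return pd.DataFrame({
            "compound_id": [f"c{i}" for i in range(n)],
            "kinase_id": ["k"] * n,
            "label": rng.permutation(labels),
        })

    @staticmethod
    def deterministic_model(train_pairs):
        return None  # scoring ignores the "model"

    @staticmethod
    def deterministic_scores(model, test_pairs):
        # stable pseudo-score from the compound id digits
        return np.array([
            (int(cid[1:]) * 2654435761 % 97) / 97.0 for cid in test_pairs["compound_id"]
        ])

    def test_folds_partition_pairs(self):
        pairs = self.toy_pairs()
        folds = []

        def scorer(model, test):
            folds.append(set(test["compound_id"]))
            return self.deterministic_scores(model, test)

        kfold_cv(pairs, self.deterministic_model, scorer, k=4, seed=1)
        # k folds, mutually disjoint, union = everything; sizes differ by <= 1
        assert set().union(*folds) == set(pairs["compound_id"])
        assert sum(len(s) for s in folds) == len(pairs)
        sizes = sorted(len(s) for s in folds)
        assert sizes[-1] - sizes[0] <= 1

    def test_same_seed_same_folds(self):
        pairs = self.toy_pairs()
        r1 = kfold_cv(pairs, self.deterministic_model, self.deterministic_scores, k=5, seed=3)
        r2 = kfold_cv(pairs, self.deterministic_model, self.deterministic_scores, k=5, seed=3)
        assert [rep.auc for rep in r1[1]] == [rep.auc for rep in r2[1]]

    def test_mean_recombines_fold_metrics(self):
        pairs = self.toy_pairs(seed=2)
        mean_rep, fold_reps = kfold_cv(
            pairs, self.deterministic_model, self.deterministic_scores, k=2, seed=5
        )
        assert len(fold_reps) == 2
        assert mean_rep.auc == pytest.approx((fold_reps[0].auc + fold_reps[1].auc) / 2)

    def test_k_validation(self):
        with pytest.raises(ValueError):
            kfold_cv(self.toy_pairs(), self.deterministic_model,
                     self.deterministic_scores, k=1)


class TestLocalEvaluate:
    def test_unweighted_mean(self):
        tasks = {
            "kA": (np.array([0.9, 0.8, 0.2, 0.1]), np.array([1, 1, 0, 0])),  # AUC 1.0
            "kB": (np.array([0.6, 0.5, 0.6, 0.5]), np.array([1, 0, 0, 1])),  # AUC 0.5
        }
        mean_rep, per_task, skipped = local_evaluate(tasks)
        assert per_task["kA"].auc == 1.0
        assert per_task["kB"].auc == 0.5
        assert mean_rep.auc == pytest.approx(0.75)
        assert skipped == []

    def test_single_class_task_skipped(self):
        tasks = {
            "good": (np.array([0.9, 0.1]), np.array([1, 0])),
            "degenerate": (np.array([0.9, 0.8]), np.array([1, 1])),
        }
        _, per_task, skipped = local_evaluate(tasks)
        assert skipped == ["degenerate"]
        assert list(per_task) == ["good"]

    def test_mean_recombines_task_values(self):
        rng = np.random.default_rng(11)
        tasks = {}
        for i in range(20):
            labels = np.array([1, 1, 0, 0] * 3)
            tasks[f"k{i:02d}"] = (rng.random(12), labels)
        mean_rep, per_task, _ = local_evaluate(tasks)
        assert mean_rep.auc == pytest.approx(np.mean([r.auc for r in per_task.values()]))

    def test_all_degenerate_rejected(self):
        with pytest.raises(ValueError):
            local_evaluate({"k": (np.array([0.5]), np.array([1]))})


class TestSweep:
    def test_shape_and_consistency(self):
        calls = []

        def bench(overrides):
            calls.append(overrides)
            return MetricsReport(
                auc=0.5 + 0.1 * overrides["inner_steps"], aupr=0.5, ba=0.5,
                precision=0.5, recall=0.5, f1=0.5, n_pos=1, n_neg=1,
            )

        result = sweep("inner_steps", [1, 2], bench)
        assert len(result.reports) == 2
        assert calls == [{"inner_steps": 1}, {"inner_steps": 2}]
        frame = result.to_frame()
        assert list(frame["inner_steps"]) == [1, 2]
        assert frame["auc"].tolist() == [0.6, 0.7]

    def test_validation(self):
        with pytest.raises(ValueError):
            sweep("nonsense", [1], lambda o: None)
        with pytest.raises(ValueError):
            sweep("inner_lr", [], lambda o: None)
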