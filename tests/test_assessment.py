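import numpy as np
import pytest
from scipy import stats

from emgassess import (
    ClinicalScores,
    GestureLabel,
    LabeledDataset,
    auc,
    binarize_label,
    build_task_dataset,
    compare_models,
    compute_metrics,
    fit_lda,
    gesture_sets,
    run_repeated_holdout,
    summarize,
)
from emgassess.exceptions import ProtocolError
from emgassess.features import BUILTIN_TASKS

import oracles as O

TASKS = {t.name: t for t in BUILTIN_TASKS}


class TestBinarize:
    @pytest.mark.parametrize(
        "task,scores,expected",
        [
            ("FMA_UE>44", ClinicalScores("a", 45, 4, 0.0), 1),
            ("FMA_UE>44", ClinicalScores("a", 44, 4, 0.0), 0),  # strict boundary
            ("FMA_UE>29", ClinicalScores("a", 30, 4, 0.0), 1),
            ("BRS>3", ClinicalScores("a", 30, 4, 0.0), 1),
            ("BRS>3", ClinicalScores("a", 30, 3, 0.0), 0),
            ("MAS>0", ClinicalScores("a", 30, 3, 1.5), 1),  # "1+" is above 0
            ("MAS>0", ClinicalScores("a", 30, 3, 0.0), 0),
        ],
    )
    def test_strict_threshold(self, task, scores, expected):
        assert binarize_label(scores, TASKS[task]) == expected


class TestLda:
    def test_separated_gaussians_high_training_accuracy(self):
        rng = np.random.default_rng(0)
        x0 = rng.normal(0.0, 1.0, size=(200, 4))
        x1 = rng.normal(5.0, 1.0, size=(200, 4))
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], 200)
        model = fit_lda(x, y)
        assert np.mean(model.predict(x) == y) >= 0.99

    def test_null_cross_validated_accuracy_near_chance(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(400, 4))
        y = np.repeat([0, 1], 200)
        perm = rng.permutation(400)
        x, y = x[perm], y[perm]
        accs = []
        for k in range(5):
            test = np.arange(400) % 5 == k
            model = fit_lda(x[~test], y[~test])
            accs.append(np.mean(model.predict(x[test]) == y[test]))
        assert 0.35 <= np.mean(accs) <= 0.65

    def test_1d_boundary_at_class_midpoint(self):
        rng = np.random.default_rng(2)
        x0 = rng.normal(0.0, 1.0, size=(5000, 1))
        x1 = rng.normal(4.0, 1.0, size=(5000, 1))
        x = np.vstack([x0, x1])
        y = np.repeat([0, 1], 5000)
        model = fit_lda(x, y)
        scores = model.decision_scores(np.linspace(-2, 6, 2001)[:, None])
        boundary = np.linspace(-2, 6, 2001)[np.argmin(np.abs(scores))]
        assert boundary == pytest.approx(2.0, abs=0.1)

    def test_single_class_training_rejected(self):
        with pytest.raises(ProtocolError):
            fit_lda(np.ones((10, 2)), np.zeros(10, dtype=int))

    def test_matches_sklearn_ranking(self):
        # independent route: sklearn's LDA must rank test points identically
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        rng = np.random.default_rng(3)
        x = np.vstack([rng.normal(0, 1, (100, 6)), rng.normal(1.0, 1, (100, 6))])
        y = np.repeat([0, 1], 100)
        xt = rng.normal(0.5, 1, (50, 6))
        mine = fit_lda(x, y, ridge=1e-9).decision_scores(xt)
        ref = LinearDiscriminantAnalysis(solver="lsqr").fit(x, y).decision_function(xt)
        assert stats.spearmanr(mine, ref).statistic == pytest.approx(1.0)
        assert np.all((mine > 0) == (ref > 0))


class TestMetrics:
    def test_worked_confusion_example(self):
        # TP=8, FN=2, TN=7, FP=3
        labels = [1] * 10 + [0] * 10
        scores = [1.0] * 8 + [-1.0] * 2 + [-1.0] * 7 + [1.0] * 3
        m = compute_metrics(labels, scores)
        assert (m.tp, m.fn, m.tn, m.fp) == (8, 2, 7, 3)
        assert m.acc == pytest.approx(0.75)
        assert m.rec == pytest.approx(0.8)
        assert m.prec == pytest.approx(8 / 11)
        assert m.spec == pytest.approx(0.7)
        assert m.f1 == pytest.approx(2 * (8 / 11) * 0.8 / (8 / 11 + 0.8))

    def test_all_correct(self):
        m = compute_metrics([1, 1, 0, 0], [1.0, 2.0, -1.0, -2.0])
        for name in ("acc", "rec", "prec", "spec", "f1"):
            assert getattr(m, name) == 1.0

    def test_single_class_test_set_flags_undefined(self):
        m = compute_metrics([1, 1, 1], [1.0, -1.0, 1.0])
        assert np.isnan(m.spec)          # no negatives present
        assert np.isnan(m.auc_roc)
        m2 = compute_metrics([0, 0], [-1.0, -1.0])
        assert np.isnan(m2.prec)         # nothing predicted positive

    def test_metric_identities_on_random_confusions(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 50))
            labels = rng.integers(0, 2, size=n)
            scores = rng.normal(size=n)
            if len(np.unique(labels)) < 2:
                continue
            m = compute_metrics(labels, scores)
            total = m.tp + m.tn + m.fp + m.fn
            assert total == n
            assert m.acc * total == pytest.approx(m.tp + m.tn)
            if not (np.isnan(m.prec) or np.isnan(m.rec) or m.prec + m.rec == 0):
                assert m.f1 == pytest.approx(
                    stats.hmean([m.prec, m.rec]), rel=1e-12
                )


class TestAuc:
    def test_perfect_ranking(self):
        value, _ = auc([1, 1, 0, 0], [0.9, 0.8, 0.3, 0.2], "ROC")
        assert value == 1.0

    def test_partial_ranking_worked_example(self):
        value, _ = auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2], "ROC")
        assert value == pytest.approx(0.75)

    def test_average_precision_worked_example(self):
        value, _ = auc([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.2], "PRC")
        assert value == pytest.approx(0.5 * 1.0 + 0.5 * (2 / 3))

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(8)
        labels = rng.integers(0, 2, size=10_000)
        scores = rng.normal(size=10_000)
        value, _ = auc(labels, scores, "ROC")
        assert value == pytest.approx(0.5, abs=0.02)

    def test_single_class_undefined(self):
        value, pts = auc([1, 1], [0.2, 0.4], "ROC")
        assert np.isnan(value) and pts is None

    def test_trapezoid_equals_concordance_with_ties(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            labels = rng.integers(0, 2, size=n)
            if len(np.unique(labels)) < 2:
                continue
            scores = np.round(rng.normal(size=n), 1)  # force ties
            value, _ = auc(labels, scores, "ROC")
            assert value == pytest.approx(O.o_concordance_auc(labels, scores), abs=1e-12)

    def test_equals_mann_whitney_statistic(self, rng):
        labels = rng.integers(0, 2, size=200)
        scores = rng.normal(size=200)
        value, _ = auc(labels, scores, "ROC")
        n1 = labels.sum()
        n0 = len(labels) - n1
        u = stats.mannwhitneyu(scores[labels == 1], scores[labels == 0]).statistic
        assert value == pytest.approx(u / (n1 * n0), abs=1e-12)


def _toy_dataset(n_subjects=8, attempts=6, dim=4, effect=3.0, seed=0):
    rng = np.random.default_rng(seed)
    xs, ys, sids = [], [], []
    for i in range(n_subjects):
        label = i % 2
        mu = effect * label
        xs.append(rng.normal(mu, 1.0, size=(attempts, dim)))
        ys.extend([label] * attempts)
        sids.extend([f"S{i:02d}"] * attempts)
    return LabeledDataset(
        BUILTIN_TASKS[0], (GestureLabel.R,), np.vstack(xs), np.array(ys), np.array(sids)
    )


class TestRepeatedHoldout:
    def test_train_test_subject_disjointness(self):
        ds = _toy_dataset()
        iters = run_repeated_holdout(ds, n_iter=30, seed=4)
        all_subjects = set(ds.subjects)
        for m in iters:
            assert set(m.test_subjects) <= all_subjects
            assert len(m.test_subjects) == 2
            # all attempts of test subjects were scored
            expected = sum(np.sum(ds.subject_ids == s) for s in m.test_subjects)
            assert m.tp + m.fp + m.tn + m.fn == expected

    def test_same_seed_reproduces_metrics(self):
        ds = _toy_dataset()
        a = run_repeated_holdout(ds, n_iter=20, seed=5)
        b = run_repeated_holdout(ds, n_iter=20, seed=5)
        assert [m.test_subjects for m in a] == [m.test_subjects for m in b]
        np.testing.assert_array_equal([m.acc for m in a], [m.acc for m in b])

    def test_strong_separation_high_accuracy(self):
        ds = _toy_dataset(effect=5.0)
        iters = run_repeated_holdout(ds, n_iter=50, seed=6)
        assert np.mean([m.acc for m in iters]) >= 0.9

    def test_subject_aggregation_mode(self):
        ds = _toy_dataset()
        iters = run_repeated_holdout(ds, n_iter=10, seed=7, aggregation="subject")
        for m in iters:
            assert m.tp + m.fp + m.tn + m.fn == 2  # one vote per test subject

    def test_too_few_subjects_rejected(self):
        ds = _toy_dataset(n_subjects=3)
        with pytest.raises(ProtocolError):
            run_repeated_holdout(ds, n_iter=5, seed=8)


class TestSubjectKfold:
    def test_each_subject_tested_exactly_once(self):
        from emgassess import run_subject_kfold

        ds = _toy_dataset(n_subjects=10)
        iters = run_subject_kfold(ds, n_folds=5, seed=14)
        tested = [s for m in iters for s in m.test_subjects]
        assert sorted(tested) == sorted(ds.subjects)

    def test_fold_count_and_disjointness(self):
        from emgassess import run_subject_kfold

        ds = _toy_dataset(n_subjects=10)
        iters = run_subject_kfold(ds, n_folds=5, seed=15)
        assert len(iters) == 5
        sets = [set(m.test_subjects) for m in iters]
        for a, b in zip(sets, sets[1:]):
            assert not (a & b)


class TestSummarize:
    def test_mean_and_sample_sd(self):
        ds = _toy_dataset()
        iters = run_repeated_holdout(ds, n_iter=2, seed=9)
        iters[0].acc, iters[1].acc = 0.8, 0.6
        s = summarize(iters)
        assert s.means["acc"] == pytest.approx(0.7)
        assert s.sds["acc"] == pytest.approx(np.std([0.8, 0.6], ddof=1))

    def test_undefined_values_excluded_and_counted(self):
        ds = _toy_dataset()
        iters = run_repeated_holdout(ds, n_iter=10, seed=10)
        iters[3].auc_roc = float("nan")  # force at least one undefined value
        vals = np.array([m.auc_roc for m in iters])
        s = summarize(iters)
        assert s.undefined_counts["auc_roc"] == int(np.isnan(vals).sum()) >= 1
        assert s.means["auc_roc"] == pytest.approx(np.nanmean(vals))

    def test_curve_bands_on_grid(self):
        ds = _toy_dataset()
        s = summarize(run_repeated_holdout(ds, n_iter=10, seed=11))
        assert s.roc_band.shape == (101, 3)
        assert s.prc_band.shape == (101, 3)
        assert s.roc_band[0, 0] == 0.0 and s.roc_band[-1, 0] == 1.0


class TestCompareModels:
    def test_exact_small_sample_p(self):
        u, p, stars = compare_models([1, 2, 3], [4, 5, 6])
        assert u == 0.0
        assert p == pytest.approx(0.1)
        assert stars == ""

    def test_identical_samples_p_near_one(self):
        rng = np.random.default_rng(12)
        a = rng.normal(size=50)
        _, p, stars = compare_models(a, a)
        assert p > 0.9
        assert stars == ""

    def test_strong_difference_flagged(self):
        rng = np.random.default_rng(13)
        a = rng.normal(0, 1, size=100)
        b = rng.normal(2, 1, size=100)
        _, p, stars = compare_models(a, b)
        assert p < 0.001 and stars == "***"


class TestGestureSets:
    def test_7_singles_and_21_pairs(self):
        sets = gesture_sets()
        singles = [s for s in sets if len(s) == 1]
        pairs = [s for s in sets if len(s) == 2]
        assert len(singles) == 7
        assert len(pairs) == 21
        # unordered: each pair appears exactly once
        assert len({frozenset(p) for p in pairs}) == 21


class TestBuildTaskDataset:
    def test_labels_match_binarized_scores(self, small_feature_table, small_cohort):
        task = TASKS["FMA_UE>29"]
        ds = build_task_dataset(small_feature_table, small_cohort.scores, task, ("R",))
        for sid in ds.subjects:
            expected = binarize_label(small_cohort.scores[sid], task)
            assert np.all(ds.y[ds.subject_ids == sid] == expected)

    def test_pair_rows_pair_attempts(self, small_feature_table, small_cohort):
        task = TASKS["BRS>3"]
        ds1 = build_task_dataset(small_feature_table, small_cohort.scores, task, ("R",))
        ds2 = build_task_dataset(
            small_feature_table, small_cohort.scores, task, ("R", "F")
        )
        assert ds2.x.shape[1] == 28  # passive on R (8) + active on F (20)
        # pairing truncates to the shorter attempt list per subject
        for sid in ds2.subjects:
            n_pairs = np.sum(ds2.subject_ids == sid)
            n_rest = np.sum(
                (small_feature_table["subject_id"] == sid)
                & (small_feature_table["label"] == "R")
            )
            n_fist = np.sum(
                (small_feature_table["subject_id"] == sid)
                & (small_feature_table["label"] == "F")
            )
            assert n_pairs == min(n_rest, n_fist)
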