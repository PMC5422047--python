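import numpy as np
import pandas as pd
import pytest

import wearact as w

# published winner-by-setting grid (8 sensor positions x feature counts
# 1..19) used as input for the best-algorithm frequency summary
WINNERS = {
    "side_waist": ["NB"] * 19,
    "front_waist": "BN NB NB NB NN 3NN SVM SVM SVM NB NB NB SVM SVM SVM SVM SVM SVM SVM".split(),
    "chest": ["NB"] * 19,
    "thigh": "BN BN 3NN 3NN NN NN 1NN NN NN 1NN 1NN 1NN 1NN 1NN 1NN 1NN NN NN NN".split(),
    "head": "NB NB NB 3NN 1NN NB NB NB NN NB NB NB NB NB NB NB NB NB NB".split(),
    "upper_arm": "NB NB NB 3NN NN 3NN 3NN 3NN SVM 3NN 3NN 3NN 3NN 3NN 3NN 3NN 3NN SVM SVM".split(),
    "wrist": "NN NN 3NN 3NN 3NN NN NN PART NN NN SVM NN SVM SVM SVM SVM SVM NN NN".split(),
    "ankle": ["NB"] * 19,
}


def _separable_table(n_subjects=6, per_class=8, noise=0.01, seed=0):
    """Feature table with classes at distinct means -> perfectly separable."""
    rng = np.random.default_rng(seed)
    classes = list(w.ACTIVITIES[:3])
    rows = []
    for s in range(n_subjects):
        for ci, c in enumerate(classes):
            X = rng.normal(10.0 * ci, noise, size=(per_class, 19))
            for t, x in enumerate(X):
                rows.append([f"S{s:02d}", c, float(t)] + list(x))
    return pd.DataFrame(
        rows, columns=["subject", "label", "start_time"] + list(w.FEATURE_NAMES)
    )


RANKING = list(w.FEATURE_NAMES)


class TestFoldPlan:
    def test_twelve_subjects_six_folds(self):
        ids = [f"S{i:02d}" for i in range(12)]
        plan = w.make_subject_folds(ids, 6, seed=0)
        assert len(plan) == 6
        tests = [set(te) for _, te in plan]
        assert all(len(t) == 2 for t in tests)
        # disjoint and exhaustive partition; train is the complement
        assert set().union(*tests) == set(ids)
        assert sum(len(t) for t in tests) == 12
        for tr, te in plan:
            assert set(tr) | set(te) == set(ids)
            assert not set(tr) & set(te)

    def test_seed_reproducibility(self):
        ids = list("abcdefgh")
        assert w.make_subject_folds(ids, 4, seed=9) == w.make_subject_folds(
            ids, 4, seed=9
        )
        assert w.make_subject_folds(ids, 4, seed=1) != w.make_subject_folds(
            ids, 4, seed=2
        )

    def test_more_folds_than_subjects_rejected(self):
        with pytest.raises(ValueError, match="folds"):
            w.make_subject_folds(["a", "b"], 3, seed=0)


class TestCrossValidate:
    def test_separable_features_give_perfect_accuracy(self):
        table = _separable_table()
        plan = w.make_subject_folds(sorted(set(table.subject)), 3, seed=0)
        for algo in ("NB", "1NN", "3NN"):
            report = w.cross_validate(table, algo, RANKING, 5, plan)
            assert report.macro_accuracy == 100.0
            for cm in report.fold_confusions:
                assert np.all(cm == np.diag(np.diag(cm)))

    def test_per_class_accuracy_matches_hand_count(self):
        table = _separable_table(n_subjects=4, noise=3.0, seed=2)
        plan = w.make_subject_folds(sorted(set(table.subject)), 2, seed=0)
        report = w.cross_validate(table, "NB", RANKING, 3, plan)
        cm = report.confusion
        assert cm.sum() == len(table)
        for i, c in enumerate(report.classes):
            n_true = (table.label == c).sum()
            assert cm[i].sum() == n_true
            assert report.per_class_accuracy[c] == pytest.approx(
                100.0 * cm[i, i] / n_true
            )
        assert report.macro_accuracy == pytest.approx(
            np.mean([report.per_class_accuracy[c] for c in report.classes])
        )

    def test_no_leak_fold_model_equals_train_only_fit(self):
        table = _separable_table(n_subjects=4, noise=2.0, seed=3)
        plan = w.make_subject_folds(sorted(set(table.subject)), 2, seed=1)
        report = w.cross_validate(table, "NB", RANKING, 4, plan)
        for k, (tr_ids, te_ids) in enumerate(plan):
            tr = table[table.subject.isin(tr_ids)]
            te = table[table.subject.isin(te_ids)]
            model = w.train("NB", tr, RANKING[:4])
            pred = model.predict_table(te)
            cm = np.zeros((3, 3), dtype=int)
            pos = {c: i for i, c in enumerate(report.classes)}
            for t, p in zip(te.label, pred):
                cm[pos[t], pos[p]] += 1
            assert np.array_equal(cm, report.fold_confusions[k])

    def test_class_missing_from_training_fold_warns(self):
        table = _separable_table(n_subjects=3, per_class=4)
        # subject S00 is the only carrier of one class
        mask = (table.label == w.ACTIVITIES[2]) & (table.subject != "S00")
        table = table[~mask].reset_index(drop=True)
        plan = w.FoldPlan(
            folds=[
                (["S01", "S02"], ["S00"]),
                (["S00", "S01"], ["S02"]),
                (["S00", "S02"], ["S01"]),
            ]
        )
        with pytest.warns(UserWarning, match="absent"):
            report = w.cross_validate(table, "NB", RANKING, 2, plan)
        assert report.warnings


class TestSweepAndSummaries:
    def test_grid_shape_and_consistency(self):
        table = _separable_table(n_subjects=4, noise=4.0, seed=5)
        plan = w.make_subject_folds(sorted(set(table.subject)), 2, seed=0)
        fvals = [1, 3, 5]
        grid = w.sweep(table, ["NB", "1NN"], RANKING, plan, f_values=fvals)
        assert grid.shape == (2, 3)
        cell = w.cross_validate(table, "NB", RANKING, 3, plan).macro_accuracy
        assert grid.loc["NB", 3] == cell
        assert len(grid.mean(axis=0)) == 3

    def test_full_feature_set_invariant_to_ranking_order(self, small_table):
        plan = w.make_subject_folds(sorted(set(small_table.subject)), 3, seed=0)
        ranked = w.relieff_weights(small_table).ranking
        a = w.cross_validate(small_table, "NB", ranked, 19, plan)
        b = w.cross_validate(small_table, "NB", RANKING, 19, plan)
        assert a.macro_accuracy == pytest.approx(b.macro_accuracy, abs=1e-9)

    def test_best_setting_rules(self):
        grid = pd.DataFrame(
            [[90.0, 95.0, 95.0]], index=["NB"], columns=[5, 10, 15]
        )
        assert w.best_setting(grid) == ("NB", 10, 95.0)  # tie -> smaller f
        grid2 = pd.DataFrame(
            [[95.0], [95.0]], index=["NB", "1NN"], columns=[7]
        )
        assert w.best_setting(grid2)[0] == "NB"  # tie -> first algorithm
        single = pd.DataFrame([[88.0]], index=["3NN"], columns=[2])
        assert w.best_setting(single) == ("3NN", 2, 88.0)

    def test_best_setting_matches_exhaustive_scan(self, rng):
        grid = pd.DataFrame(
            rng.uniform(50, 100, size=(3, 19)),
            index=["NB", "1NN", "3NN"],
            columns=range(1, 20),
        )
        algo, f, acc = w.best_setting(grid)
        assert acc == grid.to_numpy().max()
        assert grid.loc[algo, f] == acc

    def test_macro_average_all_perfect(self):
        assert w.macro_average([100.0] * 7) == 100.0

    def test_class_accuracy_summary_rounding(self):
        report = w.EvalReport(
            classes=["a", "b"],
            confusion=np.array([[99, 1], [2, 98]]),
        )
        summary = w.class_accuracy_summary(report)
        assert summary == {"a": 99.0, "b": 98.0, "average": 98.5}

    def test_best_algorithm_frequency_published_grid(self):
        winners = pd.DataFrame(WINNERS).T
        counts = w.best_algorithm_frequency(winners)
        assert counts.idxmax() == "NB"
        assert counts.sum() == 8 * 19
        assert counts.index[0] == "NB"

    def test_single_winner_everywhere(self):
        winners = pd.DataFrame([["NB"] * 4] * 3)
        counts = w.best_algorithm_frequency(winners)
        assert counts.to_dict() == {"NB": 12}
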