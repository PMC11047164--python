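import numpy as np
import pandas as pd
import pytest
import xgboost as xgb

from swayn1 import classify as C


def _toy_table(n_subjects=3, n_per=60, separation=0.0, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for si in range(n_subjects):
        for _ in range(n_per):
            label = int(rng.random() < 0.4)
            base = separation * label
            rows.append({
                "subject_id": f"S{si:02d}", "label": label,
                "med_abs_copv": base + rng.normal(),
                "med_abs_sh": rng.normal(),
                "med_abs_ha": rng.normal(),
                "med_abs_ttb": rng.normal(),
            })
    return pd.DataFrame(rows)


class TestUndersample:
    def test_study_scale_counts(self):
        rng = np.random.default_rng(0)
        y = np.array([0] * 726 + [1] * 338)
        idx = C.undersample_majority(np.zeros((len(y), 1)), y, rng)
        sub = y[idx]
        assert (sub == 0).sum() == 338 and (sub == 1).sum() == 338

    def test_balanced_input_is_identity(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1] * 10)
        idx = C.undersample_majority(np.zeros((20, 1)), y, rng)
        assert np.array_equal(idx, np.arange(20))

    def test_deterministic_given_seed(self):
        y = np.array([0] * 30 + [1] * 10)
        a = C.undersample_majority(np.zeros((40, 1)), y,
                                   np.random.default_rng(7))
        b = C.undersample_majority(np.zeros((40, 1)), y,
                                   np.random.default_rng(7))
        assert np.array_equal(a, b)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            C.undersample_majority(np.zeros((5, 1)), np.ones(5),
                                   np.random.default_rng(0))


class TestMetrics:
    def test_perfect_scores(self):
        acc, sens, auc = C.compute_metrics([1, 1, 0, 0], [0.9, 0.8, 0.1, 0.2])
        assert (acc, sens, auc) == (1.0, 1.0, 1.0)

    def test_all_negative_scores_on_balanced_set(self):
        acc, sens, auc = C.compute_metrics([1, 1, 0, 0], [0.0, 0.0, 0.0, 0.0])
        assert acc == 0.5 and sens == 0.0

    def test_worked_auc_example(self):
        _, _, auc = C.compute_metrics([1, 1, 0, 0], [0.9, 0.4, 0.6, 0.1])
        assert auc == pytest.approx(0.75)

    def test_auc_matches_all_pairs_brute_force(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        scores = np.round(rng.random(50), 1)  # ties on purpose
        _, _, auc = C.compute_metrics(y, scores)
        pos, neg = scores[y == 1], scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert auc == pytest.approx(wins / (len(pos) * len(neg)))

    def test_single_class_auc_missing(self):
        _, _, auc = C.compute_metrics([1, 1], [0.2, 0.9])
        assert np.isnan(auc)


class TestShap:
    def _fit(self, X, y):
        model = xgb.XGBClassifier(n_estimators=30, max_depth=3,
                                  learning_rate=0.3, n_jobs=1, random_state=0)
        model.fit(X, y)
        return model

    def test_constant_feature_gets_zero_importance(self):
        rng = np.random.default_rng(2)
        X = np.column_stack([rng.normal(size=300), np.full(300, 1.0)])
        y = (X[:, 0] > 0).astype(int)
        rep = C.shap_importance(self._fit(X, y), X, ["signal", "flat"])
        assert rep.mean_abs_shap["flat"] == pytest.approx(0.0, abs=1e-9)
        assert rep.ranking[0] == "signal"

    def test_informative_feature_ranked_first_with_direction(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(400, 3))
        y = (X[:, 1] > 0).astype(int)
        rep = C.shap_importance(self._fit(X, y), X, ["a", "b", "c"])
        assert rep.ranking[0] == "b"
        assert rep.direction["b"] == 1

    def test_local_accuracy_sums_to_margin_output(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(200, 4))
        y = (X[:, 0] + 0.5 * X[:, 2] > 0).astype(int)
        model = self._fit(X, y)
        phi, base = C.shap_values(model, X)
        margin = model.predict(X, output_margin=True)
        assert np.max(np.abs(phi.sum(axis=1) + base - margin)) < 1e-5

    def test_non_tree_model_rejected(self):
        with pytest.raises(TypeError):
            C.shap_importance(object(), np.zeros((2, 2)))


class TestLoso:
    grid = C.HyperGrid.reduced()

    def test_leaky_feature_is_perfectly_classified(self):
        tab = _toy_table(n_subjects=3, n_per=40)
        tab["med_abs_copv"] = tab["label"].astype(float)  # oracle leak
        res = C.loso_evaluate(tab, "copv", grid=self.grid, repeats=1, seed=0)
        assert np.mean([r.accuracy for r in res]) > 0.95

    def test_no_subject_leakage_and_balanced_tests(self):
        tab = _toy_table(n_subjects=4, n_per=40, separation=1.0)
        res = C.loso_evaluate(tab, "all4", grid=self.grid, repeats=2, seed=1,
                              keep_indices=True)
        subj = tab["subject_id"].to_numpy()
        y = tab["label"].to_numpy()
        for r in res:
            train_subjects = set(subj[r.train_index])
            test_subjects = set(subj[r.test_index])
            assert r.left_out_subject not in train_subjects
            assert test_subjects == {r.left_out_subject}
            y_te = y[r.test_index]
            assert (y_te == 1).sum() == (y_te == 0).sum()
            y_tr = y[r.train_index]
            assert (y_tr == 1).sum() == (y_tr == 0).sum()

    def test_deterministic_given_seed(self):
        tab = _toy_table(n_subjects=3, n_per=40, separation=1.0)
        a = C.loso_evaluate(tab, "ttb", grid=self.grid, repeats=2, seed=5)
        b = C.loso_evaluate(tab, "ttb", grid=self.grid, repeats=2, seed=5)
        assert [(r.accuracy, r.auc, r.best_params) for r in a] == \
               [(r.accuracy, r.auc, r.best_params) for r in b]

    def test_single_class_subject_skipped_with_warning(self):
        tab = _toy_table(n_subjects=3, n_per=30, separation=1.0)
        tab.loc[tab["subject_id"] == "S00", "label"] = 1
        with pytest.warns(UserWarning, match="single class"):
            res = C.loso_evaluate(tab, "all4", grid=self.grid, repeats=1,
                                  seed=2)
        assert {r.left_out_subject for r in res} == {"S01", "S02"}

    def test_unknown_feature_set_rejected(self):
        with pytest.raises(ValueError):
            C.loso_evaluate(_toy_table(), "nope")


class TestCompare:
    def _results(self, name, mean, sd, n=100, seed=0):
        rng = np.random.default_rng(seed)
        return [C.CVRunResult(left_out_subject="S", repeat_index=i,
                              feature_set=name, best_params={},
                              accuracy=float(rng.normal(mean, sd)),
                              sensitivity=0.5, auc=0.5, n_test=10)
                for i in range(n)]

    def test_clearly_different_sets_flagged(self):
        res = (self._results("ttb", 0.70, 0.01, seed=1)
               + self._results("copv", 0.58, 0.01, seed=2))
        out = C.compare_models(res)
        assert "copv~ttb" in out["significant"]["accuracy"]

    def test_similar_sets_not_flagged(self):
        res = (self._results("ttb", 0.70, 0.05, seed=3)
               + self._results("copv", 0.70, 0.05, seed=4))
        out = C.compare_models(res)
        assert "copv~ttb" not in out["significant"]["accuracy"]
        assert out["p_values"]["accuracy"]["copv~ttb"] > 0.005

    def test_table_covers_all_sets_and_metrics(self):
        res = sum((self._results(n, 0.6, 0.02, n=5, seed=i)
                   for i, n in enumerate(C.FEATURE_SETS)), [])
        out = C.compare_models(res)
        assert set(out["table"]) == set(C.FEATURE_SETS)
        for row in out["table"].values():
            assert set(row) == {"accuracy", "sensitivity", "auc"}
        assert len(out["p_values"]["accuracy"]) == 10
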