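"""Leave-one-subject-out (LOSO) prediction of N1 occurrence from epoch
features, with gradient-boosted trees, class balancing, inner grid search,
and Shapley-value feature importance.

Protocol, per (left-out subject, repeat): the left-out subject's epochs are
balanced by randomly undersampling their majority class to form the test set;
the remaining subjects' epochs are pooled and undersampled the same way to
form the training set; an inner stratified 5-fold grid search over the
XGBoost hyperparameters (tree depth, number of estimators, learning rate)
selects the configuration with the best mean validation accuracy (ties go to
the simplest model); the winner is refit on the full balanced pool and scored
on the test set with accuracy, sensitivity, and rank-based AUC.  Balanced
test sets make 50% the chance level for every metric based on accuracy.

Feature importance uses exact TreeSHAP attributions computed by the boosted
ensemble itself (per-sample contributions that sum, with the base value, to
the model's margin output), summarized as the mean |Shapley value| per
feature plus the sign of the feature–attribution association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats as sps
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold

from .features import FEATURE_COLUMNS

__all__ = [
    "HyperGrid",
    "CVRunResult",
    "ImportanceReport",
    "FEATURE_SETS",
    "undersample_majority",
    "compute_metrics",
    "loso_evaluate",
    "shap_importance",
    "compare_models",
]

#: Feature subsets evaluated against each other (single parameters and the
#: combined four-parameter model).
FEATURE_SETS = {
    "ha": ["med_abs_ha"],
    "sh": ["med_abs_sh"],
    "copv": ["med_abs_copv"],
    "ttb": ["med_abs_ttb"],
    "all4": list(FEATURE_COLUMNS),
}
_SET_INDEX = {name: i for i, name in enumerate(FEATURE_SETS)}

SIGNIFICANCE_P = 0.005  # Bonferroni-style level for the ten pairwise tests


@dataclass(frozen=True)
class HyperGrid:
    """XGBoost hyperparameter grid.  Defaults span depth 2–10, 60–220
    estimators, and learning rates 0.001/0.01/0.1."""

    depths: tuple = (2, 4, 6, 8, 10)
    n_estimators: tuple = (60, 100, 140, 180, 220)
    learning_rates: tuple = (0.001, 0.01, 0.1)

    def __post_init__(self) -> None:
        if not (self.depths and self.n_estimators and self.learning_rates):
            raise ValueError("grid lists must be non-empty")

    @classmethod
    def reduced(cls) -> "HyperGrid":
        """Small grid for desk-scale runs; still exercises depth selection."""
        return cls(depths=(2, 4), n_estimators=(60,), learning_rates=(0.1,))

    def as_param_grid(self) -> dict:
        return {
            "max_depth": list(self.depths),
            "n_estimators": list(self.n_estimators),
            "learning_rate": list(self.learning_rates),
        }


@dataclass
class CVRunResult:
    """Metrics and choices for one (left-out subject, repeat) evaluation."""

    left_out_subject: str
    repeat_index: int
    feature_set: str
    best_params: dict
    accuracy: float
    sensitivity: float
    auc: float
    n_test: int
    importance: "ImportanceReport | None" = None
    train_index: np.ndarray | None = None
    test_index: np.ndarray | None = None


@dataclass(frozen=True)
class ImportanceReport:
    """Mean |Shapley value| per feature (descending) and the sign of the
    association between feature value and model output."""

    mean_abs_shap: dict
    direction: dict

    @property
    def ranking(self) -> list:
        return sorted(self.mean_abs_shap, key=self.mean_abs_shap.get, reverse=True)


def undersample_majority(X: np.ndarray, y: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Indices of a balanced subset: the minority class kept whole, the
    majority class sampled uniformly without replacement to the same size."""
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("both classes must be present")
    minority = classes[np.argmin(counts)]
    n_min = counts.min()
    keep = [np.flatnonzero(y == minority)]
    for c in classes:
        if c == minority:
            continue
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=n_min, replace=False))
    return np.sort(np.concatenate(keep))


def compute_metrics(y_true, y_score, threshold: float = 0.5) -> tuple:
    """(accuracy, sensitivity, AUC) with class 1 positive.

    AUC is the rank-based (Mann–Whitney) area computed from the scores, with
    tie correction; it is NaN when only one class is present.
    """
    y_true = np.asarray(y_true)
    y_score = np.asarray(y_score, dtype=float)
    y_pred = (y_score >= threshold).astype(int)
    accuracy = float(np.mean(y_pred == y_true))
    n_pos = int(np.sum(y_true == 1))
    sensitivity = float(np.sum((y_pred == 1) & (y_true == 1)) / n_pos) if n_pos else float("nan")
    if np.unique(y_true).size < 2:
        auc = float("nan")
    else:
        auc = float(roc_auc_score(y_true, y_score))
    return accuracy, sensitivity, auc


def _make_model(params: dict, seed: int) -> xgb.XGBClassifier:
    return xgb.XGBClassifier(
        objective="binary:logistic",
        eval_metric="logloss",
        tree_method="hist",
        n_jobs=1,
        random_state=seed,
        **params,
    )


def _select_best(cv_results: dict) -> dict:
    """Best mean validation accuracy; ties broken toward the simplest model
    (smaller depth, then fewer estimators, then smaller learning rate)."""
    scores = cv_results["mean_test_score"]
    params = cv_results["params"]
    order = sorted(
        range(len(params)),
        key=lambda i: (-scores[i], params[i]["max_depth"],
                       params[i]["n_estimators"], params[i]["learning_rate"]),
    )
    return params[order[0]]


def loso_evaluate(feature_table: pd.DataFrame, feature_set: str,
                  grid: HyperGrid | None = None, repeats: int = 10,
                  seed: int = 0, permute_labels: bool = False,
                  collect_importance: bool = False,
                  keep_indices: bool = False) -> list:
    """Run the full LOSO protocol; returns one :class:`CVRunResult` per
    (subject, repeat).

    ``permute_labels`` shuffles the class labels (with a per-run seed) before
    any balancing or training — the chance-level control in which every
    metric should hover at 50%.  Per-run undersampling/permutation streams
    derive from (seed, subject, repeat) only, so different feature sets see
    identical subsets; the model seed additionally folds in the feature set.
    """
    if feature_set not in FEATURE_SETS:
        raise ValueError(f"unknown feature set '{feature_set}'")
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    grid = grid or HyperGrid()
    cols = FEATURE_SETS[feature_set]
    subjects = sorted(feature_table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("LOSO needs at least 2 subjects")
    X_all = feature_table[cols].to_numpy(dtype=float)
    y_orig = feature_table["label"].to_numpy(dtype=int)
    subj_col = feature_table["subject_id"].to_numpy()

    results = []
    for si, subj in enumerate(subjects):
        for rep in range(repeats):
            run_ss = np.random.SeedSequence(entropy=seed, spawn_key=(si, rep))
            rng = np.random.default_rng(run_ss)
            model_seed = int(
                np.random.SeedSequence(
                    entropy=seed, spawn_key=(si, rep, _SET_INDEX[feature_set])
                ).generate_state(1)[0] % (2**31)
            )
            y_all = rng.permutation(y_orig) if permute_labels else y_orig

            test_mask = subj_col == subj
            if np.unique(y_all[test_mask]).size < 2:
                warnings.warn(f"left-out subject {subj} has a single class; "
                              f"(subject, repeat)=({subj}, {rep}) skipped")
                continue
            test_pool = np.flatnonzero(test_mask)
            test_idx = test_pool[undersample_majority(
                X_all[test_pool], y_all[test_pool], rng)]
            train_pool = np.flatnonzero(~test_mask)
            train_idx = train_pool[undersample_majority(
                X_all[train_pool], y_all[train_pool], rng)]

            X_tr, y_tr = X_all[train_idx], y_all[train_idx]
            X_te, y_te = X_all[test_idx], y_all[test_idx]

            inner_cv = StratifiedKFold(n_splits=5, shuffle=True,
                                       random_state=model_seed % (2**31))
            search = GridSearchCV(
                _make_model({}, model_seed), grid.as_param_grid(),
                scoring="accuracy", cv=inner_cv, refit=False, n_jobs=1,
            )
            search.fit(X_tr, y_tr)
            best = _select_best(search.cv_results_)
            model = _make_model(best, model_seed)
            model.fit(X_tr, y_tr)
            scores = model.predict_proba(X_te)[:, 1]
            acc, sens, auc = compute_metrics(y_te, scores)

            importance = None
            if collect_importance:
                # global importance is summarized over the balanced training
                # pool (the data the fitted ensemble actually explains)
                importance = shap_importance(model, X_tr, feature_names=cols)
            results.append(CVRunResult(
                left_out_subject=subj,
                repeat_index=rep,
                feature_set=feature_set,
                best_params=dict(best),
                accuracy=acc,
                sensitivity=sens,
                auc=auc,
                n_test=int(len(test_idx)),
                importance=importance,
                train_index=train_idx if keep_indices else None,
                test_index=test_idx if keep_indices else None,
            ))
    return results


def shap_importance(model, X, feature_names: list | None = None) -> ImportanceReport:
    """Exact TreeSHAP importance for a fitted gradient-boosted tree ensemble.

    Per-sample Shapley values are computed by the booster itself
    (``pred_contribs``); they satisfy local accuracy — contributions plus the
    base value equal the model's margin output.  The report carries the mean
    |Shapley value| per feature and, as a direction summary, the sign of the
    Pearson correlation between feature values and their attributions.
    """
    if not isinstance(model, xgb.XGBModel):
        raise TypeError("shap_importance requires a fitted xgboost tree ensemble")
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        raise ValueError("X must be non-empty")
    names = list(feature_names) if feature_names is not None else [
        f"f{i}" for i in range(X.shape[1])]
    booster = model.get_booster()
    contribs = booster.predict(xgb.DMatrix(X, feature_names=names),
                               pred_contribs=True)
    phi = contribs[:, :-1]  # last column is the base value
    mean_abs = {n: float(np.mean(np.abs(phi[:, j]))) for j, n in enumerate(names)}
    direction = {}
    for j, n in enumerate(names):
        xj, pj = X[:, j], phi[:, j]
        if xj.std() == 0 or pj.std() == 0:
            direction[n] = 0
        else:
            direction[n] = int(np.sign(np.corrcoef(xj, pj)[0, 1]))
    return ImportanceReport(mean_abs_shap=mean_abs, direction=direction)


def shap_values(model, X, feature_names: list | None = None) -> tuple:
    """Raw per-sample Shapley values and base values (margin scale)."""
    if not isinstance(model, xgb.XGBModel):
        raise TypeError("shap_values requires a fitted xgboost tree ensemble")
    X = np.asarray(X, dtype=float)
    names = list(feature_names) if feature_names is not None else None
    contribs = model.get_booster().predict(
        xgb.DMatrix(X, feature_names=names), pred_contribs=True)
    return contribs[:, :-1], contribs[:, -1]


def compare_models(results: list) -> dict:
    """Mean ± SE per feature set per metric, plus all pairwise independent
    t-tests across run-level values, flagged at p < 0.005."""
    df = pd.DataFrame([{
        "feature_set": r.feature_set, "accuracy": r.accuracy,
        "sensitivity": r.sensitivity, "auc": r.auc,
    } for r in results])
    sets = [s for s in FEATURE_SETS if s in set(df["feature_set"])]
    if len(sets) < 2:
        raise ValueError("need results for at least 2 feature sets")
    metrics = ["accuracy", "sensitivity", "auc"]
    table = {}
    for s in sets:
        sub = df[df["feature_set"] == s]
        if len(sub) < 2:
            raise ValueError(f"feature set '{s}' has fewer than 2 runs")
        table[s] = {
            m: {"mean": float(sub[m].mean()),
                "se": float(sub[m].std(ddof=1) / np.sqrt(len(sub)))}
            for m in metrics
        }
    pvals = {m: {} for m in metrics}
    flags = {m: [] for m in metrics}
    for m in metrics:
        for s1, s2 in combinations(sets, 2):
            a = df.loc[df["feature_set"] == s1, m].dropna()
            b = df.loc[df["feature_set"] == s2, m].dropna()
            _, p = sps.ttest_ind(a, b)
            key = f"{s1}~{s2}"
            pvals[m][key] = float(p)
            if p < SIGNIFICANCE_P:
                flags[m].append(key)
    return {"table": table, "p_values": pvals,
            "significant": flags, "alpha": SIGNIFICANCE_P}
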