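"""Nested cross-validated random-forest difficulty classification.

Per view a random forest classifies *easy* vs *difficult* cases.  The outer
loop is leave-one-case-out (all views of a case travel together); the inner
loop is label-stratified 3-fold cross-validation repeated 3 times.  The
hyperparameter grid — number of trees, maximum sample fraction, tree depth
and the number of embedded-selected features — is searched exhaustively,
scored by the mean view-level inner-validation AUC; the winning cell is
refit on the full outer-training set and scored on the held-out case.
View probabilities are fused to case level by maximum probability.

Feature selection is the random-forest embedded method: a forest is fit on
all features, features are ranked by mean-decrease-impurity importance, and
the top k are kept (ties broken by registry order).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import RepeatedStratifiedKFold

from .errors import InputError
from .roc import auc

__all__ = ["HyperGrid", "FoldPlan", "CasePrediction", "EmbeddedSelectRF",
           "embedded_select", "select_views", "nested_cv", "fuse_max"]

ALL_VIEWS = ("LCC", "RCC", "LMLO", "RMLO")


@dataclass(frozen=True)
class HyperGrid:
    n_trees: tuple[int, ...] = (50, 100, 500, 1000)
    max_sample_fraction: tuple[float, ...] = (0.10, 0.50, 1.00)
    max_depth: tuple[int, ...] = (1, 5, 10)
    n_selected_features: tuple[int, ...] = (8, 16, 32, 64, 203)

    def cells(self):
        """Exhaustive enumeration; k varies fastest so rankings are reused."""
        return [
            {"n_trees": t, "max_sample_fraction": s, "max_depth": d, "k": k}
            for t, s, d, k in itertools.product(
                self.n_trees, self.max_sample_fraction, self.max_depth,
                self.n_selected_features)
        ]

    @classmethod
    def reduced(cls, ks=(16, 203)):
        """Small grid for demos and smoke runs (100 trees, depth 5, full sample)."""
        return cls(n_trees=(100,), max_sample_fraction=(1.0,), max_depth=(5,),
                   n_selected_features=tuple(ks))


@dataclass(frozen=True)
class FoldPlan:
    """Case-level fold layout: LOO outside, stratified 3x3 inside."""

    seed: int = 0
    inner_splits: int = 3
    inner_repeats: int = 3

    def inner_seed(self, outer_index: int) -> int:
        return int(np.random.SeedSequence((self.seed, 2, outer_index)).generate_state(1)[0] % (2 ** 31))

    def rf_seed(self, outer_index: int, channel: str) -> int:
        tag = sum(ord(ch) for ch in channel)
        return int(np.random.SeedSequence((self.seed, 3, outer_index, tag)).generate_state(1)[0] % (2 ** 31))


@dataclass
class CasePrediction:
    case_id: str
    view_probs: dict[str, float]
    fused: float
    fold_index: int
    label: int | None = None
    train_case_ids: tuple[str, ...] = ()   # fold-membership audit trail


def _fit_forest(X, y, n_trees, max_depth, max_sample_fraction, seed):
    return RandomForestClassifier(
        n_estimators=n_trees, max_depth=max_depth,
        max_samples=max_sample_fraction if max_sample_fraction < 1.0 else None,
        random_state=seed, n_jobs=1,
    ).fit(X, y)


def _rank_features(X: np.ndarray, y: np.ndarray, n_trees, max_depth, max_sample_fraction, seed,
                   return_forest: bool = False):
    """Importance ranking (descending); ties broken by registry (column) order."""
    rf = _fit_forest(X, y, n_trees, max_depth, max_sample_fraction, seed)
    order = np.argsort(-rf.feature_importances_, kind="stable")
    return (order, rf) if return_forest else order


def embedded_select(X, y, k: int, n_trees=100, max_depth=5, max_sample_fraction=1.0, seed=0):
    """Top-k feature indices by RF mean-decrease-impurity importance."""
    X = np.asarray(X, dtype=float)
    if k < 1:
        raise InputError("k must be >= 1")
    if k > X.shape[1]:
        raise InputError(f"k={k} exceeds {X.shape[1]} available features")
    order = _rank_features(X, np.asarray(y), n_trees, max_depth, max_sample_fraction, seed)
    return np.sort(order[:k])


class EmbeddedSelectRF(ClassifierMixin, BaseEstimator):
    """Random forest with embedded top-k importance feature selection.

    ``fit`` ranks all features with a forest, keeps the top ``k`` and refits
    on the reduced matrix; prediction uses only the selected columns.
    """

    def __init__(self, k: int = 203, n_trees: int = 100, max_depth: int = 5,
                 max_sample_fraction: float = 1.0, random_state: int = 0):
        self.k = k
        self.n_trees = n_trees
        self.max_depth = max_depth
        self.max_sample_fraction = max_sample_fraction
        self.random_state = random_state

    def fit(self, X, y, feature_order=None):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if self.k < 1:
            raise InputError("k must be >= 1")
        k = min(self.k, X.shape[1])
        if k == X.shape[1]:
            # full feature set: the ranking forest is the final model
            self.support_ = np.arange(X.shape[1])
            self.estimator_ = _fit_forest(X, y, self.n_trees, self.max_depth,
                                          self.max_sample_fraction, self.random_state)
        else:
            if feature_order is None:
                feature_order = _rank_features(X, y, self.n_trees, self.max_depth,
                                               self.max_sample_fraction, self.random_state)
            self.support_ = np.sort(np.asarray(feature_order)[:k])
            self.estimator_ = _fit_forest(X[:, self.support_], y, self.n_trees,
                                          self.max_depth, self.max_sample_fraction,
                                          self.random_state)
        self.classes_ = self.estimator_.classes_
        return self

    def predict_proba(self, X):
        X = np.asarray(X, dtype=float)
        return self.estimator_.predict_proba(X[:, self.support_])

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]


def select_views(cancer: bool, lesion_side: str | None, basis: str) -> list[str]:
    """Views feeding the models: all four for FP, lesion-side pair otherwise."""
    if basis == "FP":
        return list(ALL_VIEWS)
    if basis not in ("FN", "location"):
        raise InputError(f"unknown basis {basis!r}")
    if not cancer:
        raise InputError(f"basis {basis} applies to cancer cases only")
    if lesion_side not in ("L", "R"):
        raise InputError("cancer case lacks lesion side metadata")
    return [f"{lesion_side}CC", f"{lesion_side}MLO"]


def fuse_max(view_probs) -> float:
    """Maximum-probability fusion of per-view difficulty probabilities."""
    probs = list(view_probs)
    if not probs:
        raise InputError("fuse_max requires at least one view probability")
    return float(max(probs))


def _proba_difficult(model: EmbeddedSelectRF, X: np.ndarray) -> np.ndarray:
    proba = model.predict_proba(X)
    idx = int(np.nonzero(model.classes_ == 1)[0][0])
    return proba[:, idx]


def nested_cv(
    channel_features: dict[str, pd.DataFrame],
    labels: pd.Series,
    grid: HyperGrid | None = None,
    plan: FoldPlan | None = None,
) -> tuple[list[CasePrediction], list[dict]]:
    """Leave-one-case-out nested cross-validation with max fusion.

    Parameters
    ----------
    channel_features
        Mapping from view channel (e.g. ``LCC`` or lesion-side ``CC``) to a
        feature DataFrame indexed by case_id.  Every channel must cover all
        labelled cases.
    labels
        Binary Series indexed by case_id (1 = difficult, 0 = easy).

    Returns (pooled predictions, per-fold chosen-hyperparameter log).
    """
    grid = grid or HyperGrid()
    plan = plan or FoldPlan()
    case_ids = list(labels.index)
    y = labels.to_numpy()
    if len(case_ids) < 6:
        raise InputError("nested_cv needs at least 6 cases")
    if len(np.unique(y)) < 2:
        raise InputError("both classes must be present")
    mats = {}
    for ch, df in channel_features.items():
        missing = [c for c in case_ids if c not in df.index]
        if missing:
            raise InputError(f"channel {ch} missing cases: {missing[:5]}")
        mats[ch] = df.loc[case_ids].to_numpy(dtype=float)

    # group grid cells by forest params so one ranking serves every k
    rf_key = lambda cell: (cell["n_trees"], cell["max_sample_fraction"], cell["max_depth"])
    by_rf: dict[tuple, list[int]] = {}
    cells = grid.cells()
    for cell in cells:
        by_rf.setdefault(rf_key(cell), []).append(cell["k"])

    predictions, log = [], []
    n = len(case_ids)
    for outer in range(n):
        train_idx = np.array([i for i in range(n) if i != outer])
        y_tr = y[train_idx]
        inner = RepeatedStratifiedKFold(
            n_splits=plan.inner_splits, n_repeats=plan.inner_repeats,
            random_state=plan.inner_seed(outer))
        splits = list(inner.split(np.zeros(len(train_idx)), y_tr))
        view_probs = {}
        for ch, X in mats.items():
            X_tr = X[train_idx]
            seed = plan.rf_seed(outer, ch)
            scores: dict[tuple, list[float]] = {}
            n_feat = X.shape[1]
            for (t, s, d), ks in by_rf.items():
                for tr, va in splits:
                    if len(np.unique(y_tr[va])) < 2:
                        continue  # stratification should prevent this
                    order, rank_forest = _rank_features(X_tr[tr], y_tr[tr], t, d, s, seed,
                                                        return_forest=True)
                    for k in ks:
                        if k >= n_feat:
                            # selecting every feature: the ranking forest is the model
                            forest, sup = rank_forest, slice(None)
                        else:
                            sup = np.sort(order[:k])
                            forest = _fit_forest(X_tr[tr][:, sup], y_tr[tr], t, d, s, seed)
                        col = int(np.nonzero(forest.classes_ == 1)[0][0])
                        p = forest.predict_proba(X_tr[va][:, sup])[:, col]
                        scores.setdefault((t, s, d, k), []).append(auc(p, y_tr[va]))
            best_cell, best_score = None, -np.inf
            for cell in cells:  # fixed order => deterministic tie-break
                key = rf_key(cell) + (cell["k"],)
                mean_auc = float(np.mean(scores[key]))
                if mean_auc > best_score:
                    best_cell, best_score = cell, mean_auc
            final = EmbeddedSelectRF(
                k=best_cell["k"], n_trees=best_cell["n_trees"],
                max_depth=best_cell["max_depth"],
                max_sample_fraction=best_cell["max_sample_fraction"],
                random_state=seed,
            ).fit(X_tr, y_tr)
            view_probs[ch] = float(_proba_difficult(final, X[outer : outer + 1])[0])
            log.append({"fold": outer, "case_id": case_ids[outer], "channel": ch,
                        "inner_auc": best_score, **best_cell})
        predictions.append(CasePrediction(
            case_id=case_ids[outer], view_probs=view_probs,
            fused=fuse_max(view_probs.values()), fold_index=outer,
            label=int(y[outer]),
            train_case_ids=tuple(case_ids[i] for i in train_idx),
        ))
    return predictions, log


def pooled_scores(predictions: list[CasePrediction]):
    """(fused scores, labels) pooled over all outer folds for one ROC curve."""
    scores = np.array([p.fused for p in predictions])
    labels = np.array([p.label for p in predictions])
    return scores, labels
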