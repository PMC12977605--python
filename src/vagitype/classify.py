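"""Classifiers for subspecies and community state types.

Two fitted objects assign new samples:

* per-species random forests predict the mgSs of an eligible sample from
  its binary VOG profile (out-of-bag error recorded at train time, 10-fold
  cross-validation alongside);
* nearest-centroid assignment by Yue-Clayton theta places a sample
  composition into the mgCST whose centroid it most resembles, reporting
  theta as a confidence score together with the runner-up.

Concordance between hierarchical mgCST labels and centroid assignments is
estimated by stratified 10-fold cross-validation: centroids are rebuilt
from each training fold, test samples assigned, and the pooled confusion
matrix summarized by misclassification error and weighted kappa.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import StratifiedKFold

from .community_types import _centroids
from .presence import ABSENT, ELIGIBLE, MGSS0

DEFAULT_N_TREES = 500


# ---------------------------------------------------------------------------
# Yue-Clayton theta
# ---------------------------------------------------------------------------

def yue_clayton_theta(p, q) -> float:
    """Proportion-overlap similarity between two composition vectors.

    theta = sum(p*q) / (sum(p^2) + sum(q^2) - sum(p*q)), in [0, 1], equal
    to 1 iff p == q; weighting by products of proportions emphasizes
    high-abundance units. Vectors must be non-negative and sum to 1
    (aligned on the union of units; missing units are zeros).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("composition vectors must be aligned")
    if (p < 0).any() or (q < 0).any():
        raise ValueError("negative proportions")
    if p.sum() <= 0 or q.sum() <= 0:
        raise ValueError("zero-sum composition vector")
    cross = float(np.dot(p, q))
    denom = float(np.dot(p, p) + np.dot(q, q) - cross)
    return cross / denom


# ---------------------------------------------------------------------------
# Per-species random forest for mgSs
# ---------------------------------------------------------------------------

class SubspeciesRandomForest(ClassifierMixin, BaseEstimator):
    """Random forest over binary VOG features predicting mgSs labels.

    Thin estimator around :class:`sklearn.ensemble.RandomForestClassifier`
    (bootstrap, sqrt(m) features per split) that records the out-of-bag
    misclassification rate ``oob_error_`` at fit time.
    """

    def __init__(self, n_estimators=DEFAULT_N_TREES, max_features="sqrt", random_state=None):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        y = np.asarray(y)
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) < 2:
            raise ValueError("need >= 2 subspecies classes to train a forest")
        if (counts < 2).any():
            raise ValueError("every subspecies needs >= 2 training samples")
        self.feature_names_in_ = np.asarray(X.columns)
        self.forest_ = RandomForestClassifier(
            n_estimators=self.n_estimators,
            max_features=self.max_features,
            oob_score=True,
            bootstrap=True,
            random_state=self.random_state,
        ).fit(X.to_numpy(), y)
        self.classes_ = self.forest_.classes_
        self.oob_error_ = 1.0 - float(self.forest_.oob_score_)
        return self

    def predict(self, X):
        X = _align_features(pd.DataFrame(X), self.feature_names_in_)
        return self.forest_.predict(X.to_numpy())

    def cross_validate(self, X, y, n_folds=10, seed=0) -> float:
        """Stratified k-fold misclassification rate (90/10 splits at the
        default), averaged over folds."""
        X = pd.DataFrame(X).to_numpy()
        y = np.asarray(y)
        n_folds = _effective_folds(y, n_folds)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        errors = []
        for train, test in skf.split(X, y):
            clf = RandomForestClassifier(
                n_estimators=self.n_estimators,
                max_features=self.max_features,
                random_state=self.random_state,
            ).fit(X[train], y[train])
            errors.append(float(np.mean(clf.predict(X[test]) != y[test])))
        return float(np.mean(errors))


def train_mgss_forest(
    pa: pd.DataFrame, labels: pd.Series, n_trees=DEFAULT_N_TREES, seed=None
) -> SubspeciesRandomForest:
    """Train on a VOG x sample presence table and per-sample mgSs labels."""
    X = pa.T.loc[labels.index]
    return SubspeciesRandomForest(n_estimators=n_trees, random_state=seed).fit(
        X, labels.to_numpy()
    )


def assign_mgss(sample_vog_pa: pd.Series, forest: SubspeciesRandomForest, state: str):
    """mgSs label for one (species, sample): forest prediction when the
    sample is eligible, the mgSs 0 placeholder when the species is detected
    below the genome-coverage bar, and None when absent."""
    if state == ABSENT:
        return None
    if state == MGSS0:
        return 0
    if state != ELIGIBLE:
        raise ValueError(f"unknown eligibility state {state!r}")
    X = pd.DataFrame([sample_vog_pa])
    missing = set(forest.feature_names_in_) - set(X.columns)
    extra = set(X.columns) - set(forest.feature_names_in_)
    if missing or extra:
        raise ValueError(
            f"feature mismatch with trained forest (missing={sorted(missing)[:3]}, "
            f"extra={sorted(extra)[:3]})"
        )
    return int(forest.predict(X)[0])


def _align_features(X: pd.DataFrame, features) -> pd.DataFrame:
    return X.reindex(columns=list(features), fill_value=0)


# ---------------------------------------------------------------------------
# Nearest-centroid mgCST assignment
# ---------------------------------------------------------------------------

@dataclass
class McgstAssignment:
    sample_id: str
    mgcst: int
    theta: float
    runner_up: int | None
    runner_up_theta: float
    tie: bool = False


class ThetaCentroidClassifier(ClassifierMixin, BaseEstimator):
    """Nearest-centroid classifier under Yue-Clayton theta similarity.

    ``fit(X, y)`` computes per-class centroids as mean relative abundances
    (rows renormalized); ``predict`` assigns each sample to the centroid of
    maximal theta, ties broken by lowest class index.
    """

    def __init__(self):
        pass

    def fit(self, X, y):
        X = pd.DataFrame(X)
        self.centroids_ = _centroids(X, np.asarray(y))
        self.classes_ = self.centroids_.index.to_numpy()
        return self

    def predict(self, X):
        return assign_mgcst_frame(pd.DataFrame(X), self.centroids_)["mgcst"].to_numpy()

    def theta_matrix(self, X) -> pd.DataFrame:
        """Theta of every sample (rows) against every centroid (columns)."""
        return _theta_matrix(pd.DataFrame(X), self.centroids_)


def _theta_matrix(comp: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    # unseen units are dropped and samples renormalized: centroids cannot
    # score units absent from training
    aligned = comp.reindex(columns=centroids.columns, fill_value=0.0)
    totals = aligned.sum(axis=1)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with empty composition after alignment: {bad}")
    aligned = aligned.div(totals, axis=0)
    P = aligned.to_numpy(dtype=float)
    C = centroids.to_numpy(dtype=float)
    cross = P @ C.T
    denom = (P**2).sum(axis=1)[:, None] + (C**2).sum(axis=1)[None, :] - cross
    return pd.DataFrame(cross / denom, index=comp.index, columns=centroids.index)


def assign_mgcst_frame(comp: pd.DataFrame, centroids: pd.DataFrame) -> pd.DataFrame:
    """Vectorized assignment of many samples; columns: mgcst, theta,
    runner_up, runner_up_theta, tie."""
    theta = _theta_matrix(comp, centroids)
    order = np.argsort(-theta.to_numpy(), axis=1, kind="stable")
    classes = theta.columns.to_numpy()
    best = classes[order[:, 0]]
    best_theta = theta.to_numpy()[np.arange(len(comp)), order[:, 0]]
    if theta.shape[1] > 1:
        runner = classes[order[:, 1]]
        runner_theta = theta.to_numpy()[np.arange(len(comp)), order[:, 1]]
        tie = np.isclose(best_theta, runner_theta)
    else:
        runner = np.full(len(comp), -1)
        runner_theta = np.full(len(comp), np.nan)
        tie = np.zeros(len(comp), dtype=bool)
    return pd.DataFrame(
        {
            "mgcst": best.astype(int),
            "theta": best_theta,
            "runner_up": runner,
            "runner_up_theta": runner_theta,
            "tie": tie,
        },
        index=comp.index,
    )


def assign_mgcst(sample_comp: pd.Series, model) -> McgstAssignment:
    """Assign one sample composition to an mgCST of a fitted model."""
    centroids = model.centroids if hasattr(model, "centroids") else model.centroids_
    frame = assign_mgcst_frame(pd.DataFrame([sample_comp]), centroids)
    row = frame.iloc[0]
    return McgstAssignment(
        sample_id=str(sample_comp.name),
        mgcst=int(row["mgcst"]),
        theta=float(row["theta"]),
        runner_up=int(row["runner_up"]) if row["runner_up"] >= 0 else None,
        runner_up_theta=float(row["runner_up_theta"]),
        tie=bool(row["tie"]),
    )


# ---------------------------------------------------------------------------
# Cross-validated concordance
# ---------------------------------------------------------------------------

@dataclass
class CrossValidationResult:
    confusion: pd.DataFrame  # rows: hierarchical (expected); cols: centroid (observed)
    misclassification: float  # mean per-fold error rate
    weighted_kappa: float  # linear weights, pooled confusion
    kappa: float  # unweighted Cohen kappa, pooled
    fold_kappas: list[float]
    n_folds: int


def _effective_folds(y: np.ndarray, n_folds: int) -> int:
    smallest = int(np.bincount(pd.factorize(y)[0]).min())
    if smallest < n_folds:
        warnings.warn(
            f"smallest class has {smallest} samples < {n_folds} folds; "
            f"fold count reduced to {max(2, smallest)}",
            stacklevel=3,
        )
        return max(2, smallest)
    return n_folds


def crossvalidate_mgcst(
    comp: pd.DataFrame, labels: pd.Series, n_folds: int = 10, seed: int = 0
) -> CrossValidationResult:
    """Stratified k-fold CV of nearest-centroid mgCST assignment.

    Per fold, centroids are rebuilt from the training samples only and the
    held-out samples assigned by maximal theta. The pooled confusion matrix
    compares hierarchical labels (expected) with centroid assignments
    (observed); misclassification error is the average proportion of
    incorrect assignments across folds; concordance is linear-weighted
    kappa on the pooled table (unweighted kappa also reported).
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    labels = pd.Series(labels, dtype=int).loc[comp.index]
    y = labels.to_numpy()
    n_folds = _effective_folds(y, n_folds)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    expected_all, observed_all = [], []
    fold_errors, fold_kappas = [], []
    for train, test in skf.split(np.zeros(len(y)), y):
        clf = ThetaCentroidClassifier().fit(comp.iloc[train], y[train])
        pred = clf.predict(comp.iloc[test])
        truth = y[test]
        expected_all.append(truth)
        observed_all.append(pred)
        fold_errors.append(float(np.mean(pred != truth)))
        if len(np.unique(truth)) > 1 or len(np.unique(pred)) > 1:
            fold_kappas.append(
                float(cohen_kappa_score(truth, pred, weights="linear"))
            )
    expected = np.concatenate(expected_all)
    observed = np.concatenate(observed_all)
    confusion = pd.crosstab(
        pd.Series(expected, name="hierarchical"),
        pd.Series(observed, name="centroid"),
        dropna=False,
    )
    all_classes = sorted(set(expected) | set(observed))
    confusion = confusion.reindex(index=all_classes, columns=all_classes, fill_value=0)
    return CrossValidationResult(
        confusion=confusion,
        misclassification=float(np.mean(fold_errors)),
        weighted_kappa=float(cohen_kappa_score(expected, observed, weights="linear")),
        kappa=float(cohen_kappa_score(expected, observed)),
        fold_kappas=fold_kappas,
        n_folds=n_folds,
    )
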