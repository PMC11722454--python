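"""Windowed depth profiles and the Short/Short vs Long/any depth classifier.

Samples carrying at least one Long VNTR allele show elevated short-read
coverage over the repeat interval (extra repeat copies map onto the single
reference array), while Short/Short samples are flat.  The classifier
summarises per-base depth as median coverage in consecutive 50-bp windows,
normalises by the sample's flanking depth, and fits an elastic-net
penalized logistic regression with the penalty strength chosen by
cross-validated AUC.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .io import DepthTrack

POSITIVE_LABEL = "LONG_ANY"
NEGATIVE_LABEL = "SHORT_SHORT"


@dataclass
class CoverageProfile:
    """Per-window median depths over a target interval, plus flank medians."""

    sample_id: str
    window_size: int
    medians: np.ndarray
    flank_medians: np.ndarray

    @property
    def n_windows(self) -> int:
        return self.medians.size

    @property
    def n_flank_windows(self) -> int:
        return self.flank_medians.size


def _window_medians(depths: np.ndarray, window_size: int) -> np.ndarray:
    n = depths.size
    return np.array(
        [np.median(depths[lo : min(lo + window_size, n)]) for lo in range(0, n, window_size)]
    )


def window_profile(
    track: DepthTrack,
    interval: tuple[int, int],
    window_size: int = 50,
    sample_id: str = "",
) -> CoverageProfile:
    """Median depth in consecutive non-overlapping windows over ``interval``.

    The final partial window is kept.  Any track bases outside the interval
    are windowed the same way and stored as flank medians for
    normalization.
    """
    start, end = interval
    target = track.slice(start, end)  # raises if the track does not cover it
    medians = _window_medians(target, window_size)
    flank_parts = []
    if track.start < start:
        flank_parts.append(_window_medians(track.slice(track.start, start), window_size))
    if track.end > end:
        flank_parts.append(_window_medians(track.slice(end, track.end), window_size))
    flank = np.concatenate(flank_parts) if flank_parts else np.empty(0)
    return CoverageProfile(sample_id, window_size, medians, flank)


def normalize_profile(profile: CoverageProfile) -> np.ndarray:
    """Window medians divided by the sample's median flank depth.

    The resulting features are dimensionless and centred near 1 for flat
    (reference-like) samples, removing per-sample sequencing-depth scale.
    """
    if profile.n_flank_windows == 0:
        raise ValueError("no flank windows available for normalization")
    denom = float(np.median(profile.flank_medians))
    if denom <= 0:
        raise ValueError("median flank depth is zero; cannot normalize")
    return profile.medians / denom


def profile_matrix(profiles: list[CoverageProfile]) -> np.ndarray:
    """Stack normalized profiles into an ``(n_samples, n_windows)`` matrix."""
    return np.vstack([normalize_profile(p) for p in profiles])


@dataclass
class ClassMetrics:
    """Held-out classification metrics with Long/any as the positive class."""

    sensitivity: float
    specificity: float
    f1: float
    auc: float
    tp: int
    fp: int
    tn: int
    fn: int


class DepthProfileClassifier(BaseEstimator, ClassifierMixin):
    """Elastic-net logistic classifier on normalized window-median profiles.

    Parameters
    ----------
    l1_ratio : float
        Elastic-net mixing (0 = ridge, 1 = lasso).
    Cs : tuple of float
        Inverse-penalty grid searched by cross-validation (corresponding to
        penalty strengths 10^-4 .. 10^1).
    cv : int
        Number of stratified folds used to pick the penalty by AUC.
    random_state : int
        Seed for fold shuffling and the saga solver.

    Attributes
    ----------
    model_ : fitted :class:`~sklearn.linear_model.LogisticRegression`
    best_C_ : inverse penalty selected by cross-validation
    classes_ : array of the two class labels
    """

    def __init__(
        self,
        l1_ratio: float = 0.5,
        Cs: tuple = (1e-1, 1e0, 1e1, 1e2, 1e3, 1e4),
        cv: int = 5,
        random_state: int = 0,
    ):
        self.l1_ratio = l1_ratio
        self.Cs = Cs
        self.cv = cv
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one row per label")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly 2 classes, got {classes.tolist()}")
        # put the Long-carrier label last so predict_proba[:, 1] is P(Long/any)
        if POSITIVE_LABEL in classes:
            classes = np.array(
                [c for c in classes if c != POSITIVE_LABEL] + [POSITIVE_LABEL]
            )
        self.classes_ = classes
        y_bin = (y == classes[1]).astype(int)
        base = LogisticRegression(
            solver="saga",
            l1_ratio=self.l1_ratio,
            max_iter=10_000,
            random_state=self.random_state,
        )
        folds = StratifiedKFold(self.cv, shuffle=True, random_state=self.random_state)
        search = GridSearchCV(
            base, {"C": list(self.Cs)}, scoring="roc_auc", cv=folds, refit=True
        )
        search.fit(X, y_bin)
        self.model_ = search.best_estimator_
        self.best_C_ = search.best_params_["C"]
        self.cv_auc_ = float(search.best_score_)
        self.coef_ = self.model_.coef_
        self.intercept_ = self.model_.intercept_
        self.n_features_in_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "model_")
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"X has {X.shape[1]} features, model expects {self.n_features_in_}"
            )
        return self.model_.predict_proba(X)

    def predict(self, X):
        # ties at probability 0.5 resolve to the positive (Long/any) class
        proba = self.predict_proba(X)[:, 1]
        return np.where(proba >= 0.5, self.classes_[1], self.classes_[0])

    def to_json(self, path: str | Path) -> None:
        check_is_fitted(self, "model_")
        payload = {
            "format": "repeatlens-depth-classifier",
            "classes": [str(c) for c in self.classes_],
            "l1_ratio": self.l1_ratio,
            "best_C": self.best_C_,
            "coef": self.coef_.tolist(),
            "intercept": self.intercept_.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DepthProfileClassifier":
        payload = json.loads(Path(path).read_text())
        obj = cls(l1_ratio=payload["l1_ratio"])
        model = LogisticRegression(
            solver="saga", l1_ratio=payload["l1_ratio"], C=payload["best_C"],
        )
        model.classes_ = np.array([0, 1])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.intercept_ = np.asarray(payload["intercept"], dtype=float)
        obj.model_ = model
        obj.best_C_ = payload["best_C"]
        obj.classes_ = np.asarray(payload["classes"])
        obj.coef_ = model.coef_
        obj.intercept_ = model.intercept_
        obj.n_features_in_ = model.coef_.shape[1]
        return obj


def evaluate(y_true, y_pred, proba=None) -> ClassMetrics:
    """Sensitivity/specificity/F1 (Long/any positive) and rank-based AUC."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise ValueError("empty input")
    pos = y_true == POSITIVE_LABEL
    pred_pos = y_pred == POSITIVE_LABEL
    tp = int(np.sum(pos & pred_pos))
    fn = int(np.sum(pos & ~pred_pos))
    fp = int(np.sum(~pos & pred_pos))
    tn = int(np.sum(~pos & ~pred_pos))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else float("nan")
    auc = float("nan")
    if proba is not None and 0 < pos.sum() < y_true.size:
        auc = float(roc_auc_score(pos.astype(int), np.asarray(proba, dtype=float)))
    return ClassMetrics(sens, spec, f1, auc, tp, fp, tn, fn)


def train_classifier(
    features: np.ndarray,
    labels,
    train_frac: float = 0.6,
    folds: int = 5,
    seed: int = 0,
) -> tuple[DepthProfileClassifier, ClassMetrics]:
    """Stratified 60/40 split, CV-tuned fit on the training portion, and
    metrics on the untouched held-out fraction."""
    features = np.asarray(features, dtype=float)
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("training requires both classes present")
    X_tr, X_te, y_tr, y_te = train_test_split(
        features,
        labels,
        train_size=train_frac,
        stratify=labels,
        random_state=seed,
    )
    clf = DepthProfileClassifier(cv=folds, random_state=seed).fit(X_tr, y_tr)
    proba = clf.predict_proba(X_te)[:, 1]
    metrics = evaluate(y_te, clf.predict(X_te), proba)
    return clf, metrics


def predict_class(
    model: DepthProfileClassifier, features: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Class calls and Long/any probabilities for a feature matrix."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    proba = model.predict_proba(features)[:, 1]
    return model.predict(features), proba
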