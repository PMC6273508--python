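"""Receptor-subtype selectivity analysis.

Labels compounds by the difference of pKi values against two subtypes
(selectivity ratio, threshold |SR| >= 1.3 inclusive), and provides the model
validation battery: Y-randomization null distributions, repeated-resampling
stability, and a centroid-distance applicability domain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from sklearn.base import clone
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_predict

from .modeling import mcc_from_counts, confusion_counts, regression_metrics, split_train_test

DEFAULT_SR_THRESHOLD = 1.3

A_SELECTIVE = "A_selective"
B_SELECTIVE = "B_selective"
NONSELECTIVE = "nonselective"


@dataclass
class SelectivityRecord:
    molecule_id: str
    pKi_A: float
    pKi_B: float
    SR: float
    label: str


def label_selectivity(
    pKi_A: float,
    pKi_B: float,
    threshold: float = DEFAULT_SR_THRESHOLD,
    molecule_id: str = "",
) -> SelectivityRecord:
    """SR = pKi_A - pKi_B; A-selective iff SR >= threshold, B-selective iff
    SR <= -threshold (both boundaries inclusive), otherwise nonselective."""
    sr = pKi_A - pKi_B
    # epsilon keeps the boundary inclusive under floating-point subtraction
    # (e.g. 7.3 - 6.0 = 1.2999999999999998)
    eps = 1e-9
    if sr >= threshold - eps:
        label = A_SELECTIVE
    elif sr <= -threshold + eps:
        label = B_SELECTIVE
    else:
        label = NONSELECTIVE
    return SelectivityRecord(molecule_id, pKi_A, pKi_B, sr, label)


def _cv_score(model, X, y, task: str, folds: int, seed: int) -> float:
    """Headline CV score: Q2 for regression, MCC for classification."""
    if task == "regression":
        cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
        pred = cross_val_predict(clone(model), X, y, cv=cv)
        q2 = regression_metrics(y, pred, cv_pairs=(y, pred)).Q2
        return float("nan") if q2 is None else q2
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clone(model), X, y, cv=cv)
    mcc = mcc_from_counts(confusion_counts(y, pred))
    return float("nan") if mcc is None else mcc


def y_randomization(
    X: np.ndarray,
    y: np.ndarray,
    model_builder: Callable[[], object],
    n_iter: int = 500,
    seed: int = 0,
    task: str = "regression",
    folds: int = 5,
) -> dict:
    """Refit on shuffled responses ``n_iter`` times with fixed hyperparameters.

    Returns the null score distribution (Q2 or MCC via CV), the real model's
    score, and its percentile rank within the null.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    real = _cv_score(model_builder(), X, y, task, folds, seed)
    null = np.empty(n_iter)
    for i in range(n_iter):
        y_shuf = rng.permutation(y)
        null[i] = _cv_score(model_builder(), X, y_shuf, task, folds, seed)
    percentile = float(100.0 * np.mean(real > null))
    return {"real_score": real, "null_scores": null, "percentile": percentile}


def resample_stability(
    X: np.ndarray,
    y: np.ndarray,
    model_builder: Callable[[], object],
    n_iter: int = 100,
    seed: int = 0,
    task: str = "regression",
    test_fraction: float = 0.2,
) -> dict:
    """Repeated random 4:1 re-splits: fit on train, score on test each time.

    Headline metric: test R2 (regression) or MCC (classification).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    scores = np.empty(n_iter)
    for i in range(n_iter):
        tr, te = split_train_test(
            X, y, test_fraction=test_fraction, seed=seed + i,
            stratified=(task == "classification"),
        )
        model = model_builder()
        model.fit(X[tr], y[tr])
        pred = model.predict(X[te])
        if task == "regression":
            r2 = regression_metrics(y[te], pred).R2
            scores[i] = float("nan") if r2 is None else r2
        else:
            mcc = mcc_from_counts(confusion_counts(y[te], pred))
            scores[i] = float("nan") if mcc is None else mcc
    return {
        "scores": scores,
        "mean": float(np.nanmean(scores)),
        "sd": float(np.nanstd(scores, ddof=1)),
    }


@dataclass
class ApplicabilityDomain:
    """Centroid-distance domain: in-domain iff the Euclidean distance to the
    training centroid is <= mean + 3*sd of the training-point distances."""

    centroid: np.ndarray
    threshold: float

    @classmethod
    def fit(cls, X_train: np.ndarray) -> "ApplicabilityDomain":
        X_train = np.asarray(X_train, dtype=float)
        centroid = X_train.mean(axis=0)
        dists = np.linalg.norm(X_train - centroid, axis=1)
        return cls(centroid=centroid, threshold=float(dists.mean() + 3.0 * dists.std()))

    def check(self, query: np.ndarray) -> tuple[bool, float]:
        dist = float(np.linalg.norm(np.asarray(query, dtype=float) - self.centroid))
        return dist <= self.threshold, dist
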