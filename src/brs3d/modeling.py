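"""SVM modeling on descriptor tables: splits, imbalance handling, grid-searched
RBF models with 10-fold CV, classification/regression metrics, enrichment
factors, and bagged-tree permutation feature importance.

Metric conventions: ratios with a zero denominator are reported as ``None``
("undefined"), never silently as 0.  AUC is the rank-based (Mann-Whitney)
statistic with tied scores given average ranks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split
from sklearn.svm import SVC, SVR
from sklearn.tree import DecisionTreeClassifier

# standard LIBSVM grid-search recipe
DEFAULT_C_GRID = [2.0**e for e in range(-5, 16, 2)]
DEFAULT_GAMMA_GRID = [2.0**e for e in range(-15, 4, 2)]

DEFAULT_SUBSET_FRACTIONS = (0.05, 0.10, 0.30, 0.50, 0.70, 1.00)


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class ClassMetrics:
    """Accuracy, precision, recall (=sensitivity), specificity, MCC, AUC.

    ``None`` marks an undefined value (zero denominator / single-class AUC).
    """

    counts: ConfusionCounts
    ACC: float | None
    Precision: float | None
    Recall: float | None
    Specificity: float | None
    MCC: float | None
    AUC: float | None = None


@dataclass
class RegressionMetrics:
    n: int
    RMSE: float
    R2: float | None
    Q2: float | None = None


@dataclass
class ImbalanceStrategy:
    """One of full_1_39 (leave as-is), subsample_1_10 (keep 10 decoys per
    active), or weighted (per-class weights on C, default active:decoy 39:1)."""

    name: str
    seed: int = 0
    active_weight: float = 39.0
    decoy_weight: float = 1.0

    def __post_init__(self):
        if self.name not in ("full_1_39", "subsample_1_10", "weighted"):
            raise ValueError(f"unknown imbalance strategy: {self.name}")


@dataclass
class ModelSpec:
    kernel: str
    C: float
    gamma: float
    class_weight: dict | None
    folds: int
    objective: str
    cv_score: float


@dataclass
class FeatureRanking:
    importances: np.ndarray
    order: np.ndarray  # feature indices, descending importance
    fractions: tuple = DEFAULT_SUBSET_FRACTIONS

    def subset(self, fraction: float) -> np.ndarray:
        """Prefix of the ranking holding round(fraction * k) features."""
        size = int(round(fraction * len(self.order)))
        return self.order[:size]

    def subset_sizes(self) -> list[int]:
        return [int(round(f * len(self.order))) for f in self.fractions]


# ---------------------------------------------------------------------------
# splits and imbalance


def split_train_test(
    X: np.ndarray,
    y: np.ndarray,
    test_fraction: float = 0.2,
    seed: int = 0,
    stratified: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint train/test index partition, stratified by default, seeded."""
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx,
        test_size=test_fraction,
        random_state=seed,
        stratify=np.asarray(y) if stratified else None,
    )
    return np.sort(train_idx), np.sort(test_idx)


def apply_imbalance_strategy(
    X: np.ndarray, y: np.ndarray, strategy: ImbalanceStrategy
) -> tuple[np.ndarray, np.ndarray, dict | None]:
    """Return (X', y', class_weight) for the chosen strategy.

    subsample_1_10 keeps all actives plus 10 decoys per active, drawn
    uniformly without replacement using the strategy seed.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    if strategy.name == "full_1_39":
        return X, y, None
    if strategy.name == "weighted":
        return X, y, {1: strategy.active_weight, 0: strategy.decoy_weight}
    # subsample_1_10
    rng = np.random.default_rng(strategy.seed)
    active_idx = np.flatnonzero(y == 1)
    decoy_idx = np.flatnonzero(y == 0)
    n_keep = min(10 * active_idx.size, decoy_idx.size)
    kept = rng.choice(decoy_idx, size=n_keep, replace=False)
    sel = np.sort(np.concatenate([active_idx, kept]))
    return X[sel], y[sel], None


# ---------------------------------------------------------------------------
# metrics


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true).astype(int)
    y_pred = np.asarray(y_pred).astype(int)
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == 0) & (y_pred == 0))),
        FP=int(np.sum((y_true == 0) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == 0))),
    )


def _ratio(num: float, den: float) -> float | None:
    return None if den == 0 else num / den


def mcc_from_counts(c: ConfusionCounts) -> float | None:
    den = math.sqrt(
        float(c.TP + c.FP) * (c.TP + c.FN) * (c.TN + c.FP) * (c.TN + c.FN)
    )
    if den == 0:
        return None
    return (c.TP * c.TN - c.FP * c.FN) / den


def auc_score(y_true: np.ndarray, scores: np.ndarray) -> float | None:
    """Rank-based AUC (Mann-Whitney U with average ranks for ties)."""
    y_true = np.asarray(y_true).astype(int)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(y_true == 1))
    n_neg = int(np.sum(y_true == 0))
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(scores)
    u = np.sum(ranks[y_true == 1]) - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def classification_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    scores: np.ndarray | None = None,
) -> ClassMetrics:
    c = confusion_counts(y_true, y_pred)
    return ClassMetrics(
        counts=c,
        ACC=_ratio(c.TP + c.TN, c.total),
        Precision=_ratio(c.TP, c.TP + c.FP),
        Recall=_ratio(c.TP, c.TP + c.FN),
        Specificity=_ratio(c.TN, c.TN + c.FP),
        MCC=mcc_from_counts(c),
        AUC=auc_score(y_true, scores) if scores is not None else None,
    )


def regression_metrics(
    y: np.ndarray,
    y_hat: np.ndarray,
    cv_pairs: tuple[np.ndarray, np.ndarray] | None = None,
) -> RegressionMetrics:
    """RMSE and R2 on (y, y_hat); Q2 = squared Pearson correlation of the
    cross-validated (observed, predicted) pairs when supplied."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    n = y.size
    rmse = float(np.sqrt(np.sum((y - y_hat) ** 2) / n))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = None if ss_tot == 0 else float(1.0 - np.sum((y - y_hat) ** 2) / ss_tot)
    q2 = None
    if cv_pairs is not None:
        yc = np.asarray(cv_pairs[0], dtype=float)
        yp = np.asarray(cv_pairs[1], dtype=float)
        if np.std(yc) == 0 or np.std(yp) == 0:
            q2 = None
        else:
            q2 = float(np.corrcoef(yc, yp)[0, 1] ** 2)
    return RegressionMetrics(n=n, RMSE=rmse, R2=r2, Q2=q2)


def enrichment_factor(
    scores: np.ndarray, labels: np.ndarray, fraction: float
) -> float:
    """Active rate in the top ceil(fraction*N) scores over the overall active
    rate; score ties break by stable input order."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = scores.size
    n_top = math.ceil(fraction * n)
    order = np.argsort(-scores, kind="stable")
    top = labels[order[:n_top]]
    overall_rate = labels.sum() / n
    if overall_rate == 0:
        raise ValueError("no actives in the set")
    return float((top.sum() / n_top) / overall_rate)


# ---------------------------------------------------------------------------
# grid-searched SVM


def _cv_auc(X, y, C, gamma, folds, seed, class_weight) -> float:
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train, test in cv.split(X, y):
        clf = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
        clf.fit(X[train], y[train])
        scores = clf.decision_function(X[test])
        aucs.append(auc_score(y[test], scores))
    return float(np.mean(aucs))


def _cv_rmse(X, y, C, gamma, folds, seed) -> float:
    cv = KFold(n_splits=folds, shuffle=True, random_state=seed)
    sq_errors = np.empty(len(y))
    for train, test in cv.split(X):
        reg = SVR(kernel="rbf", C=C, gamma=gamma)
        reg.fit(X[train], y[train])
        sq_errors[test] = (y[test] - reg.predict(X[test])) ** 2
    return float(np.sqrt(sq_errors.mean()))


def grid_search_svm(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    objective: str = "auc",
    class_weight: dict | None = None,
    seed: int = 0,
    c_grid: list[float] | None = None,
    gamma_grid: list[float] | None = None,
):
    """Exhaustive (C, gamma) grid search for an RBF SVM.

    Classification maximizes mean stratified-CV AUC; regression minimizes
    CV RMSE.  Ties break to the smaller C, then the smaller gamma.  Returns
    (fitted model, ModelSpec).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    c_grid = sorted(c_grid or DEFAULT_C_GRID)
    gamma_grid = sorted(gamma_grid or DEFAULT_GAMMA_GRID)
    if objective not in ("auc", "rmse_cv"):
        raise ValueError(f"unknown objective: {objective}")
    if objective == "auc":
        counts = np.bincount(y.astype(int))
        if counts.min() < folds:
            raise ValueError(
                f"need >= {folds} samples per class for {folds}-fold stratified CV"
            )

    best = None  # (score_key, C, gamma, cv_score)
    for C, gamma in product(c_grid, gamma_grid):
        if objective == "auc":
            cv_score = _cv_auc(X, y, C, gamma, folds, seed, class_weight)
            key = cv_score  # maximize
        else:
            cv_score = _cv_rmse(X, y, C, gamma, folds, seed)
            key = -cv_score  # minimize
        if best is None or key > best[0]:
            best = (key, C, gamma, cv_score)

    _, C, gamma, cv_score = best
    if objective == "auc":
        model = SVC(kernel="rbf", C=C, gamma=gamma, class_weight=class_weight)
    else:
        model = SVR(kernel="rbf", C=C, gamma=gamma)
    model.fit(X, y)
    spec = ModelSpec(
        kernel="rbf",
        C=C,
        gamma=gamma,
        class_weight=class_weight,
        folds=folds,
        objective=objective,
        cv_score=cv_score,
    )
    return model, spec


# ---------------------------------------------------------------------------
# permutation feature importance (bagged trees, out-of-bag)


def rank_features_permutation(
    X: np.ndarray,
    y: np.ndarray,
    n_trees: int = 500,
    seed: int = 0,
    fractions: tuple = DEFAULT_SUBSET_FRACTIONS,
) -> FeatureRanking:
    """Permutation-accuracy importance from a bagged ensemble of decision
    trees: importance of feature j = mean decrease in out-of-bag accuracy when
    column j is shuffled.  Ranking descends; ties break to the lower index.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    n, k = X.shape
    rng = np.random.default_rng(seed)
    max_features = max(1, int(np.sqrt(k)))
    importances = np.zeros(k)
    n_scored = 0
    for t in range(n_trees):
        bag = rng.integers(0, n, n)
        oob = np.setdiff1d(np.arange(n), bag, assume_unique=False)
        if oob.size == 0:
            continue
        tree = DecisionTreeClassifier(
            max_features=max_features,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[bag], y[bag])
        X_oob = X[oob]
        y_oob = y[oob]
        base_acc = float(np.mean(tree.predict(X_oob) == y_oob))
        used = np.unique(tree.tree_.feature)
        used = used[used >= 0]  # leaves are -2
        for j in used:
            perm = rng.permutation(oob.size)
            X_perm = X_oob.copy()
            X_perm[:, j] = X_oob[perm, j]
            acc = float(np.mean(tree.predict(X_perm) == y_oob))
            importances[j] += base_acc - acc
        n_scored += 1
    # trees not using a feature contribute 0 decrease (Breiman convention)
    if n_scored:
        importances /= n_scored
    order = np.argsort(-importances, kind="stable")
    return FeatureRanking(importances=importances, order=order, fractions=fractions)
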