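import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from brs3d import fixtures, modeling
from brs3d.modeling import (
    ConfusionCounts,
    FeatureRanking,
    ImbalanceStrategy,
    apply_imbalance_strategy,
    auc_score,
    classification_metrics,
    confusion_counts,
    enrichment_factor,
    grid_search_svm,
    mcc_from_counts,
    rank_features_permutation,
    regression_metrics,
    split_train_test,
)

SMALL_C_GRID = [2.0**e for e in (-1, 3, 7)]
SMALL_GAMMA_GRID = [2.0**e for e in (-9, -5, -1)]


# ---------------------------------------------------------------------------
# independent brute-force oracles


def oracle_auc(y, scores):
    """Pair-counting AUC: wins + half-ties over all pos/neg pairs."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def oracle_metrics(tp, tn, fp, fn):
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else None
    prec = tp / (tp + fp) if tp + fp else None
    rec = tp / (tp + fn) if tp + fn else None
    spec = tn / (tn + fp) if tn + fp else None
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = (tp * tn - fp * fn) / den if den else None
    return acc, prec, rec, spec, mcc


class TestSplit:
    def test_80_20_partition_sizes(self):
        y = np.r_[np.ones(100), np.zeros(900)]
        X = np.zeros((1000, 2))
        tr, te = split_train_test(X, y, seed=3)
        assert len(tr) == 800 and len(te) == 200
        assert len(set(tr) & set(te)) == 0

    def test_stratified_proportions(self):
        y = np.r_[np.ones(40), np.zeros(960)]
        X = np.zeros((1000, 2))
        tr, _ = split_train_test(X, y, seed=1)
        assert abs(int(y[tr].sum()) - 32) <= 1

    def test_seed_determinism(self):
        y = np.r_[np.ones(20), np.zeros(80)]
        X = np.zeros((100, 2))
        a = split_train_test(X, y, seed=7)
        b = split_train_test(X, y, seed=7)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestImbalance:
    def test_subsample_ratio(self):
        y = np.r_[np.ones(5), np.zeros(195)]
        X = np.arange(200)[:, None].astype(float)
        Xs, ys, cw = apply_imbalance_strategy(X, y, ImbalanceStrategy("subsample_1_10", seed=0))
        assert int(ys.sum()) == 5 and int((ys == 0).sum()) == 50
        assert cw is None

    def test_weighted_leaves_data_unchanged(self):
        y = np.r_[np.ones(5), np.zeros(20)]
        X = np.arange(25)[:, None].astype(float)
        Xw, yw, cw = apply_imbalance_strategy(X, y, ImbalanceStrategy("weighted"))
        assert np.array_equal(Xw, X) and np.array_equal(yw, y)
        assert cw == {1: 39.0, 0: 1.0}

    def test_full_is_identity(self):
        y = np.r_[np.ones(5), np.zeros(20)]
        X = np.arange(25)[:, None].astype(float)
        Xf, yf, cw = apply_imbalance_strategy(X, y, ImbalanceStrategy("full_1_39"))
        assert np.array_equal(Xf, X) and np.array_equal(yf, y) and cw is None

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError):
            ImbalanceStrategy("oversample")


class TestGridSearch:
    def test_planted_separation_high_cv_auc(self, classification_data):
        X, y, _ = classification_data
        _, spec = grid_search_svm(
            X, y, folds=10, seed=0, c_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID
        )
        assert spec.cv_score > 0.9

    def test_shuffled_labels_near_chance(self, classification_data):
        X, y, _ = classification_data
        rng = np.random.default_rng(4)
        y_shuf = rng.permutation(y)
        _, spec = grid_search_svm(
            X, y_shuf, folds=10, seed=0,
            c_grid=[2.0], gamma_grid=SMALL_GAMMA_GRID,
        )
        assert abs(spec.cv_score - 0.5) <= 0.15

    def test_winner_matches_independent_cv_loop(self, classification_data):
        X, y, _ = classification_data
        _, spec = grid_search_svm(
            X, y, folds=5, seed=9, c_grid=SMALL_C_GRID, gamma_grid=SMALL_GAMMA_GRID
        )
        # independent CV recomputation of the winning pair with sklearn
        cv = StratifiedKFold(n_splits=5, shuffle=True, random_state=9)
        aucs = []
        for tr, te in cv.split(X, y):
            clf = SVC(kernel="rbf", C=spec.C, gamma=spec.gamma).fit(X[tr], y[tr])
            aucs.append(oracle_auc(y[te], clf.decision_function(X[te])))
        assert spec.cv_score == pytest.approx(np.mean(aucs), abs=1e-12)

    def test_too_few_per_class_errors(self):
        X = np.zeros((12, 2))
        y = np.r_[np.ones(3), np.zeros(9)]
        with pytest.raises(ValueError, match="per class"):
            grid_search_svm(X, y, folds=10)


class TestClassificationMetrics:
    def test_worked_confusion_matrix(self):
        # MCC = 270 / sqrt(13*10*40*37) = 0.615547...
        oracle = 270 / math.sqrt(13 * 10 * 40 * 37)
        c = ConfusionCounts(TP=8, TN=35, FP=5, FN=2)
        assert mcc_from_counts(c) == pytest.approx(oracle, abs=1e-12)
        assert mcc_from_counts(c) == pytest.approx(0.6156, abs=1e-4)

    def test_perfect_prediction(self):
        y = np.r_[np.ones(10), np.zeros(10)]
        m = classification_metrics(y, y)
        assert m.ACC == 1.0 and m.MCC == 1.0

    def test_auc_extremes(self):
        y = np.r_[np.ones(5), np.zeros(5)]
        scores = np.r_[np.arange(5, 10), np.arange(5)].astype(float)
        assert auc_score(y, scores) == 1.0
        assert auc_score(y, -scores) == 0.0

    def test_undefined_ratios_reported_as_none(self):
        y = np.zeros(10)
        m = classification_metrics(y, np.zeros(10))
        assert m.Precision is None and m.Recall is None and m.MCC is None
        assert m.ACC == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(10):
            n = int(rng.integers(5, 60))
            y = rng.integers(0, 2, n)
            pred = rng.integers(0, 2, n)
            scores = rng.normal(size=n)
            m = classification_metrics(y, pred, scores)
            c = m.counts
            acc, prec, rec, spec, mcc = oracle_metrics(c.TP, c.TN, c.FP, c.FN)
            for ours, ref in [(m.ACC, acc), (m.Precision, prec), (m.Recall, rec),
                              (m.Specificity, spec), (m.MCC, mcc)]:
                if ref is None:
                    assert ours is None
                else:
                    assert ours == pytest.approx(ref, abs=1e-12)
            if 0 < y.sum() < n:
                assert m.AUC == pytest.approx(oracle_auc(y, scores), abs=1e-12)

    @given(st.lists(st.tuples(st.integers(0, 1), st.integers(0, 1)), min_size=2, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_mcc_symmetric_under_class_swap(self, pairs):
        y = np.array([p[0] for p in pairs])
        pred = np.array([p[1] for p in pairs])
        a = mcc_from_counts(confusion_counts(y, pred))
        b = mcc_from_counts(confusion_counts(1 - y, 1 - pred))
        if a is None:
            assert b is None
        else:
            assert a == pytest.approx(b, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None)
    def test_auc_invariant_under_monotone_transform(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = rng.integers(0, 2, n)
        if y.sum() in (0, n):
            y[0] = 1 - y[0]
        scores = rng.normal(size=n)
        base = auc_score(y, scores)
        assert auc_score(y, np.exp(scores)) == pytest.approx(base, abs=1e-12)


class TestRegressionMetrics:
    def test_perfect_prediction(self):
        y = np.array([1.0, 2.0, 3.0])
        m = regression_metrics(y, y)
        assert m.RMSE == 0.0 and m.R2 == 1.0

    def test_constant_prediction(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        yhat = np.full(4, y.mean())
        m = regression_metrics(y, yhat, cv_pairs=(y, yhat))
        assert m.R2 == pytest.approx(0.0, abs=1e-12)
        assert m.Q2 is None  # zero-variance predictions

    def test_five_point_hand_computation(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        yhat = np.array([1.2, 1.8, 3.3, 3.9, 5.1])
        # oracle, spelled out
        rmse = math.sqrt(sum((a - b) ** 2 for a, b in zip(y, yhat)) / 5)
        ss_res = sum((a - b) ** 2 for a, b in zip(y, yhat))
        ss_tot = sum((a - y.mean()) ** 2 for a in y)
        r2 = 1 - ss_res / ss_tot
        yc, pc = y - y.mean(), yhat - yhat.mean()
        q2 = (np.sum(yc * pc) / math.sqrt(np.sum(yc**2) * np.sum(pc**2))) ** 2
        m = regression_metrics(y, yhat, cv_pairs=(y, yhat))
        assert m.RMSE == pytest.approx(rmse, abs=1e-12)
        assert m.R2 == pytest.approx(r2, abs=1e-12)
        assert m.Q2 == pytest.approx(q2, abs=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_fixtures_match_oracle(self, seed):
        rng = np.random.default_rng(seed + 1000)
        y = rng.normal(size=20)
        yhat = y + rng.normal(scale=0.3, size=20)
        m = regression_metrics(y, yhat, cv_pairs=(y, yhat))
        assert m.RMSE == pytest.approx(math.sqrt(np.mean((y - yhat) ** 2)), abs=1e-12)
        assert m.R2 == pytest.approx(
            1 - np.sum((y - yhat) ** 2) / np.sum((y - y.mean()) ** 2), abs=1e-12
        )
        assert m.Q2 == pytest.approx(np.corrcoef(y, yhat)[0, 1] ** 2, abs=1e-12)


class TestEnrichmentFactor:
    def test_perfect_ranking_closed_form(self):
        y = np.r_[np.ones(20), np.zeros(780)]
        scores = np.r_[np.full(20, 2.0), np.full(780, 1.0)]
        assert enrichment_factor(scores, y, 0.10) == pytest.approx(10.0, abs=1e-12)

    def test_bounded_by_inverse_active_fraction(self):
        rng = np.random.default_rng(2)
        y = np.r_[np.ones(20), np.zeros(780)]
        for _ in range(10):
            scores = rng.normal(size=800)
            assert enrichment_factor(scores, y, 0.10) <= 40.0 + 1e-12

    def test_random_scores_near_unity_in_expectation(self):
        rng = np.random.default_rng(3)
        y = np.r_[np.ones(50), np.zeros(450)]
        efs = [
            enrichment_factor(rng.normal(size=500), y, 0.10) for _ in range(200)
        ]
        assert np.mean(efs) == pytest.approx(1.0, abs=0.15)

    def test_ties_break_by_stable_input_order(self):
        y = np.array([1, 0, 1, 0])
        scores = np.ones(4)
        # top-2 under stable order = indices 0, 1 -> 1 active of 2
        assert enrichment_factor(scores, y, 0.5) == pytest.approx((1 / 2) / (2 / 4))

    def test_no_actives_errors(self):
        with pytest.raises(ValueError):
            enrichment_factor(np.ones(4), np.zeros(4), 0.5)


class TestFeatureRanking:
    def test_planted_dimensions_recovered(self, classification_data):
        X, y, informative = classification_data
        ranking = rank_features_permutation(X, y, n_trees=150, seed=5)
        top_m = set(ranking.order[: len(informative)].tolist())
        recovered = len(top_m & set(informative.tolist())) / len(informative)
        assert recovered >= 0.8

    def test_appended_noise_feature_ranks_low(self):
        # needs a majority-informative base table: among equally useless
        # features the appended one lands uniformly by symmetry, so the
        # bottom-half claim is only meaningful against signal-carrying dims
        table, y, _ = fixtures.make_classification_dataset(
            fixtures.DatasetSpec(
                seed=21, n_active=40, n_decoy=110, k=24, m_informative=16,
                shift=0.25, noise=0.05,
            )
        )
        X = table.matrix
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed + 500)
            X_aug = np.c_[X, rng.uniform(0, 1, len(y))]
            ranking = rank_features_permutation(X_aug, y, n_trees=60, seed=seed)
            position = int(np.where(ranking.order == X.shape[1])[0][0])
            hits += position >= X_aug.shape[1] // 2
        assert hits / n_seeds > 0.9

    def test_subset_sizes_for_k300(self):
        ranking = FeatureRanking(
            importances=np.zeros(300), order=np.arange(300)
        )
        assert ranking.subset_sizes() == [15, 30, 90, 150, 210, 300]

    def test_subsets_are_ranking_prefixes(self, classification_data):
        X, y, _ = classification_data
        ranking = rank_features_permutation(X, y, n_trees=30, seed=1)
        for frac in ranking.fractions:
            subset = ranking.subset(frac)
            assert np.array_equal(subset, ranking.order[: len(subset)])


class TestImbalanceTendency:
    def test_subsample_recall_vs_weighted_over_seeds(self):
        # statistical tendency over 20 seeds, not per-seed
        recalls = {"subsample_1_10": [], "weighted": []}
        accs = {"full_1_39": [], "subsample_1_10": []}
        for seed in range(20):
            table, y, _ = fixtures.make_classification_dataset(
                fixtures.DatasetSpec(
                    seed=seed, n_active=20, n_decoy=780, k=60,
                    m_informative=8, shift=0.15, noise=0.07,
                )
            )
            X = table.matrix
            tr, te = split_train_test(X, y, seed=seed)
            for name in ("subsample_1_10", "weighted", "full_1_39"):
                strat = ImbalanceStrategy(name, seed=seed)
                Xt, yt, cw = apply_imbalance_strategy(X[tr], y[tr], strat)
                clf = SVC(kernel="rbf", C=32.0, gamma=0.05, class_weight=cw)
                clf.fit(Xt, yt)
                m = classification_metrics(y[te], clf.predict(X[te]))
                if name in recalls:
                    recalls[name].append(m.Recall)
                if name in accs:
                    accs[name].append(m.ACC)
        assert np.mean(recalls["subsample_1_10"]) >= np.mean(recalls["weighted"])
        assert np.mean(accs["full_1_39"]) >= np.mean(accs["subsample_1_10"])
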