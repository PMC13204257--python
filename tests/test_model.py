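"""Split plans, penalized logistic fit, thresholds and metrics against oracles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from carovib.model import (
    OperatingThreshold,
    aggregate_to_side,
    assert_no_group_leakage,
    balanced_class_weights,
    collect_oof_predictions,
    evaluate,
    fit_logistic_l2,
    make_split_plan,
    predict_segment_proba,
    select_threshold,
    side_table,
    train_and_evaluate,
)


def make_groups(n_groups=40, n_pos=12, seed=0):
    rng = np.random.default_rng(seed)
    names = [f"g{i:03d}" for i in range(n_groups)]
    labels = {g: int(i < n_pos) for i, g in enumerate(names)}
    return np.array(names), labels


class TestSplitPlan:
    def test_partition_and_determinism(self):
        groups, labels = make_groups()
        p1 = make_split_plan(groups, labels, seed=3)
        p2 = make_split_plan(groups, labels, seed=3)
        assert p1 == p2
        assert set(p1.test_groups) | set(p1.train_groups) == set(groups)
        assert not set(p1.test_groups) & set(p1.train_groups)
        assert_no_group_leakage(p1)

    def test_holdout_stratification(self):
        groups, labels = make_groups(40, 12)
        plan = make_split_plan(groups, labels, test_frac=0.15, seed=1)
        n_pos_test = sum(labels[g] for g in plan.test_groups)
        assert 1 <= n_pos_test <= 2
        assert 5 <= len(plan.test_groups) <= 7

    def test_insufficient_groups_rejected(self):
        groups, labels = make_groups(8, 2)
        with pytest.raises(ValueError, match="class"):
            make_split_plan(groups, labels, k=5, seed=0)


def grid_refine_logistic(X, y, sw, lam, rounds=8, span=4.0, n=13):
    """Iteratively refined dense grid minimizer of the penalized objective."""
    from carovib.model import _objective

    p = X.shape[1]
    A = np.hstack([X, np.ones((X.shape[0], 1))])
    pen = np.r_[np.full(p, lam), 0.0]
    center = np.zeros(p + 1)
    width = span
    for _ in range(rounds):
        axes = [np.linspace(c - width, c + width, n) for c in center]
        mesh = np.meshgrid(*axes, indexing="ij")
        pts = np.stack([m.ravel() for m in mesh], axis=1)
        vals = [_objective(A, y, sw, pen, b) for b in pts]
        center = pts[int(np.argmin(vals))]
        width = 2 * width / (n - 1)
    return center


class TestLogisticFit:
    def test_separable_data_has_finite_weights(self):
        X = np.array([[0.0], [1.0], [2.0], [3.0]])
        y = np.array([0, 0, 1, 1])
        m = fit_logistic_l2(X, y, lam=1.0)
        assert np.isfinite(m.weights).all()
        assert np.abs(m.weights).max() < 50

    def test_ridge_limit_shrinks_to_base_rate(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(200, 3))
        y = (rng.uniform(size=200) < 0.3).astype(int)
        m = fit_logistic_l2(X, y, lam=1e8)
        assert np.abs(m.weights).max() < 1e-4
        # with inverse-frequency class weights the weighted base rate is 1/2
        assert m.predict_proba(X).mean() == pytest.approx(0.5, abs=0.01)

    def test_matches_grid_search_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(60, 2))
        y = (X[:, 0] + 0.5 * X[:, 1] + rng.normal(0, 1, 60) > 0).astype(int)
        m = fit_logistic_l2(X, y, lam=1.0, standardize=False)
        sw = np.where(y == 1, m.class_weights[1], m.class_weights[0])
        beta = grid_refine_logistic(X, y, sw, 1.0)
        np.testing.assert_allclose(np.r_[m.weights, m.intercept], beta, atol=1e-4)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(300, 4))
        y = (X @ np.array([1.0, -0.5, 0.2, 0.0]) + rng.normal(0, 1, 300) > 0).astype(int)
        m = fit_logistic_l2(X, y, lam=1.0, standardize=False)
        sw = np.where(y == 1, m.class_weights[1], m.class_weights[0])
        sk = LogisticRegression(C=1.0, solver="lbfgs", tol=1e-10, max_iter=5000)
        sk.fit(X, y, sample_weight=sw)
        np.testing.assert_allclose(m.weights, sk.coef_[0], atol=1e-5)
        np.testing.assert_allclose(m.intercept, sk.intercept_[0], atol=1e-5)

    def test_standardization_from_training_only(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5.0, 2.0, size=(100, 2))
        y = (X[:, 0] > 5).astype(int)
        m = fit_logistic_l2(X, y)
        np.testing.assert_allclose(m.mu, X.mean(axis=0))
        np.testing.assert_allclose(m.sigma, X.std(axis=0))


class TestAggregation:
    def test_single_segment_group(self):
        s = aggregate_to_side(np.array([0.7]), np.array(["a"]))
        assert s["a"] == 0.7

    def test_mean_and_permutation_invariance(self):
        p = np.array([0.2, 0.8, 0.5])
        g = np.array(["a", "a", "b"])
        s1 = aggregate_to_side(p, g)
        s2 = aggregate_to_side(p[::-1], g[::-1])
        assert s1["a"] == pytest.approx(0.5)
        pd.testing.assert_series_equal(s1, s2)


class TestOOF:
    def test_every_train_group_scored_once_without_leakage(self):
        groups, labels = make_groups(30, 10)
        rng = np.random.default_rng(4)
        seg_groups = np.repeat(groups, 5)
        y = np.array([labels[g] for g in seg_groups])
        X = rng.normal(size=(seg_groups.size, 3)) + y[:, None]
        plan = make_split_plan(seg_groups, labels, seed=0)
        tr = np.isin(seg_groups, plan.train_groups)
        oof = collect_oof_predictions(plan, X[tr], y[tr], seg_groups[tr])
        counts = oof.groupby("group")["fold"].nunique()
        assert set(counts.index) == set(plan.train_groups)
        assert (counts == 1).all()

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        groups, labels = make_groups(48, 16)
        shuffled = dict(zip(groups, rng.permutation([labels[g] for g in groups])))
        seg_groups = np.repeat(groups, 5)
        y = np.array([shuffled[g] for g in seg_groups])
        X = rng.normal(size=(seg_groups.size, 3))
        plan = make_split_plan(seg_groups, shuffled, seed=1)
        tr = np.isin(seg_groups, plan.train_groups)
        oof = collect_oof_predictions(plan, X[tr], y[tr], seg_groups[tr])
        sides = side_table(oof)
        auroc = roc_auc_score(sides["label"], sides["proba"])
        assert 0.35 <= auroc <= 0.65


def brute_force_threshold(probs, labels, sens_min):
    uniq = np.unique(probs)
    cands = np.concatenate([[uniq[0] / 2], (uniq[1:] + uniq[:-1]) / 2, [(uniq[-1] + 1) / 2]])
    pos = labels == 1
    feasible = []
    for tau in cands:
        pred = probs >= tau
        sens = pred[pos].mean()
        spec = (~pred[~pos]).mean()
        if sens >= sens_min:
            feasible.append((tau, sens, spec))
    best_spec = max(f[2] for f in feasible)
    winners = [f for f in feasible if f[2] == best_spec]
    return min(winners)[0], best_spec


class TestThreshold:
    def test_worked_example(self):
        probs = np.array([0.9, 0.7, 0.6, 0.2, 0.1])
        labels = np.array([1, 1, 1, 0, 0])
        th = select_threshold(probs, labels, 0.9)
        assert 0.2 < th.tau <= 0.6
        assert th.specificity == 1.0
        assert th.sensitivity == 1.0

    def test_separable_gives_full_specificity(self):
        probs = np.array([0.8, 0.9, 0.95, 0.1, 0.2])
        labels = np.array([1, 1, 1, 0, 0])
        assert select_threshold(probs, labels, 0.9).specificity == 1.0

    def test_sens_min_zero_maximizes_specificity(self):
        probs = np.array([0.3, 0.7, 0.9, 0.1, 0.6])
        labels = np.array([1, 1, 1, 0, 0])
        th = select_threshold(probs, labels, 0.0)
        tau0, spec0 = brute_force_threshold(probs, labels, 0.0)
        assert th.specificity == spec0
        assert th.tau == pytest.approx(tau0)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            n = rng.integers(5, 31)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            probs = np.round(rng.uniform(size=n), 2)  # induce ties
            th = select_threshold(probs, labels, 0.9)
            tau0, spec0 = brute_force_threshold(probs, labels, 0.9)
            assert th.specificity == pytest.approx(spec0)
            np.testing.assert_array_equal(probs >= th.tau, probs >= tau0)


def pairwise_auroc(probs, labels):
    pos = probs[labels == 1]
    neg = probs[labels == 0]
    wins = 0.0
    for a in pos:
        for b in neg:
            wins += 1.0 if a > b else (0.5 if a == b else 0.0)
    return wins / (pos.size * neg.size)


def step_aupr(probs, labels):
    """Step-wise PR integration grouping tied scores (no interpolation)."""
    order = np.argsort(-probs, kind="stable")
    p, y = probs[order], labels[order]
    n_pos = y.sum()
    tp = fp = 0
    last_recall = 0.0
    area = 0.0
    i = 0
    while i < y.size:
        j = i
        while j < y.size and p[j] == p[i]:
            j += 1
        tp += y[i:j].sum()
        fp += (j - i) - y[i:j].sum()
        recall = tp / n_pos
        precision = tp / (tp + fp)
        area += (recall - last_recall) * precision
        last_recall = recall
        i = j
    return area


class TestEvaluate:
    def test_perfect_separation(self):
        probs = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        r = evaluate(probs, labels, 0.5)
        assert r.auroc == 1.0 and r.aupr == 1.0
        assert r.sensitivity == r.specificity == 1.0
        assert sum(r.confusion.values()) == 4

    def test_all_tied_probs_give_half_auroc(self):
        r = evaluate(np.full(10, 0.5), np.array([1, 0] * 5), 0.5)
        assert r.auroc == pytest.approx(0.5)

    def test_matches_pairwise_and_step_oracles(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n = rng.integers(6, 51)
            labels = np.zeros(n, dtype=int)
            labels[: rng.integers(1, n)] = 1
            rng.shuffle(labels)
            if labels.min() == labels.max():
                continue
            probs = np.round(rng.uniform(size=n), 1)
            r = evaluate(probs, labels, 0.5)
            assert r.auroc == pytest.approx(pairwise_auroc(probs, labels), abs=1e-12)
            assert r.aupr == pytest.approx(step_aupr(probs, labels), abs=1e-12)

    def test_toy_confusion_matrix(self):
        probs = np.array([0.9, 0.4, 0.8, 0.3, 0.6, 0.1])
        labels = np.array([1, 1, 0, 0, 1, 0])
        r = evaluate(probs, labels, 0.5)
        assert r.confusion == {"tp": 2, "fp": 1, "tn": 2, "fn": 1}
        assert r.accuracy == pytest.approx(4 / 6)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate(np.array([0.4, 0.6]), np.array([1, 1]), 0.5)


class TestEndToEndProtocol:
    def test_strong_signal_recovers_discrimination(self):
        rng = np.random.default_rng(8)
        groups, labels = make_groups(40, 14)
        seg_groups = np.repeat(groups, 8)
        y = np.array([labels[g] for g in seg_groups])
        table = pd.DataFrame(
            {
                "group_key": seg_groups,
                "label": y,
                "f1": y * 2.0 + rng.normal(0, 1, y.size),
                "f2": rng.normal(size=y.size),
            }
        )
        result = train_and_evaluate(table, ["f1", "f2"], seed=0)
        assert result["side_report"].auroc >= 0.8
        assert result["threshold"].from_training_oof
        assert 0 < result["threshold"].tau < 1
        # positive effect recovered on the informative feature
        assert result["model"].weights[0] > 0
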