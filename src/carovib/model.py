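"""Grouped training, patient-side aggregation, threshold prespecification, evaluation.

The decision unit is the patient-side (one carotid artery); segments from the
same side never cross a split boundary.  Protocol:

1. stratified holdout of ~15 % of patient-side groups as a fixed test set;
2. stratified, grouped 5-fold cross-validation on the remaining groups;
3. L2-regularized logistic regression (Newton iteration, intercept
   unpenalized, inverse-frequency class weights) on features standardized
   with training statistics only;
4. patient-side probabilities = mean of the side's segment probabilities;
5. operating threshold = lowest threshold with out-of-fold training
   sensitivity >= 0.90, ties resolved toward maximum specificity, applied
   unchanged to the held-out test set;
6. AUROC / AUPR plus thresholded metrics at both segment and side resolution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_auc_score, roc_curve


# --------------------------------------------------------------------------- #
# splitting
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class SplitPlan:
    test_groups: tuple[str, ...]
    train_groups: tuple[str, ...]
    folds: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # (train, val) per fold
    seed: int


def stratified_group_kfold(
    groups: np.ndarray, group_labels: dict[str, int], k: int, seed: int
) -> list[tuple[tuple[str, ...], tuple[str, ...]]]:
    """Greedy stratified partition of groups into k folds, seeded.

    Groups are shuffled, then assigned class by class to the fold currently
    holding the fewest groups of that class (ties to the smaller fold, then to
    the lower fold index) so every fold sees both classes where possible.
    """
    rng = np.random.default_rng(seed)
    uniq = np.asarray(sorted(set(groups)))
    rng.shuffle(uniq)
    folds: list[list[str]] = [[] for _ in range(k)]
    per_class: list[dict[int, int]] = [dict() for _ in range(k)]
    for cls in sorted({group_labels[g] for g in uniq}):
        for g in [g for g in uniq if group_labels[g] == cls]:
            j = min(
                range(k),
                key=lambda i: (per_class[i].get(cls, 0), len(folds[i]), i),
            )
            folds[j].append(g)
            per_class[j][cls] = per_class[j].get(cls, 0) + 1
    out = []
    for i in range(k):
        val = tuple(sorted(folds[i]))
        train = tuple(sorted(g for j in range(k) if j != i for g in folds[j]))
        out.append((train, val))
    return out


def make_split_plan(
    groups: np.ndarray,
    group_labels: dict[str, int],
    test_frac: float = 0.15,
    k: int = 5,
    seed: int = 0,
) -> SplitPlan:
    """Stratified group holdout followed by stratified grouped k-fold."""
    uniq = sorted(set(map(str, groups)))
    labels = np.array([group_labels[g] for g in uniq])
    rng = np.random.default_rng(seed)
    test: list[str] = []
    for cls in (0, 1):
        members = [g for g, y in zip(uniq, labels) if y == cls]
        n_cls = max(1, int(round(test_frac * len(members))))
        if len(members) < 1:
            raise ValueError(f"class {cls}: no groups available for the holdout")
        test.extend(rng.choice(members, size=min(n_cls, len(members) - 1), replace=False))
    train = [g for g in uniq if g not in set(test)]
    for cls in (0, 1):
        if sum(group_labels[g] == cls for g in train) < k:
            raise ValueError(f"class {cls}: fewer than k={k} training groups; cannot stratify folds")
    folds = stratified_group_kfold(np.asarray(train), group_labels, k, seed + 1)
    return SplitPlan(
        test_groups=tuple(sorted(test)),
        train_groups=tuple(sorted(train)),
        folds=tuple(folds),
        seed=seed,
    )


def assert_no_group_leakage(plan: SplitPlan) -> None:
    """Hard guard: no group on both sides of any split."""
    if set(plan.test_groups) & set(plan.train_groups):
        raise AssertionError("group appears in both test and train")
    for train, val in plan.folds:
        if set(train) & set(val):
            raise AssertionError("group appears in both fold train and validation")
        if set(train) | set(val) != set(plan.train_groups):
            raise AssertionError("fold does not partition the training groups")


# --------------------------------------------------------------------------- #
# L2 logistic regression (Newton)
# --------------------------------------------------------------------------- #


@dataclass
class TrainedModel:
    weights: np.ndarray  # on the standardized scale
    intercept: float
    mu: np.ndarray  # training means
    sigma: np.ndarray  # training SDs
    lam: float
    class_weights: tuple[float, float]  # (w0, w1)
    feature_names: tuple[str, ...] = ()

    def standardize(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=np.float64) - self.mu) / self.sigma

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        Xs = self.standardize(X)
        if Xs.shape[1] != self.weights.size:
            raise ValueError(f"expected {self.weights.size} features, got {Xs.shape[1]}")
        return Xs @ self.weights + self.intercept

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return _sigmoid(self.decision_function(X))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=np.float64)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def balanced_class_weights(y: np.ndarray) -> tuple[float, float]:
    """Inverse class-frequency weights normalized to mean 1 over samples."""
    y = np.asarray(y)
    n = y.size
    n1 = int(y.sum())
    n0 = n - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes required for class weights")
    return n / (2.0 * n0), n / (2.0 * n1)


def fit_logistic_l2(
    X: np.ndarray,
    y: np.ndarray,
    class_weights: tuple[float, float] | None = None,
    lam: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 100,
    feature_names: tuple[str, ...] = (),
    standardize: bool = True,
) -> TrainedModel:
    """Newton minimization of the class-weighted penalized negative log-likelihood.

    Objective: sum_i w_{y_i} * log(1 + exp(-s_i z_i)) + (lam/2) * ||w||^2 with
    the intercept unpenalized; converged when the gradient's infinity norm is
    <= ``tol``.  Features are standardized internally with the statistics of
    ``X`` (training data) unless ``standardize=False``.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, p = X.shape
    if standardize:
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        sigma = np.where(sigma == 0, 1.0, sigma)
    else:
        mu = np.zeros(p)
        sigma = np.ones(p)
    Xs = (X - mu) / sigma
    if class_weights is None:
        class_weights = balanced_class_weights(y)
    sw = np.where(y == 1, class_weights[1], class_weights[0])

    beta = np.zeros(p + 1)  # [w, b]
    A = np.hstack([Xs, np.ones((n, 1))])
    pen = np.r_[np.full(p, lam), 0.0]
    for it in range(max_iter):
        z = A @ beta
        mu_hat = _sigmoid(z)
        grad = A.T @ (sw * (mu_hat - y)) + pen * beta
        if np.abs(grad).max() <= tol:
            break
        w_irls = sw * np.clip(mu_hat * (1 - mu_hat), 1e-10, None)
        H = (A * w_irls[:, None]).T @ A + np.diag(pen)
        step = np.linalg.solve(H, grad)
        # damped Newton: halve until the objective stops increasing (with a
        # float-plateau allowance so convergence does not stall near optimum)
        obj0 = _objective(A, y, sw, pen, beta)
        t = 1.0
        for _ in range(30):
            cand = beta - t * step
            if _objective(A, y, sw, pen, cand) <= obj0 + 1e-12 * (1.0 + abs(obj0)):
                break
            t *= 0.5
        beta = beta - t * step
    else:
        z = A @ beta
        grad = A.T @ (sw * (_sigmoid(z) - y)) + pen * beta
        if np.abs(grad).max() > 1e-4:
            raise RuntimeError(
                f"logistic Newton failed to converge: |grad|_inf = {np.abs(grad).max():.3g}"
            )
        warnings.warn("logistic Newton stopped at loose tolerance", RuntimeWarning)
    return TrainedModel(
        weights=beta[:p].copy(),
        intercept=float(beta[p]),
        mu=mu,
        sigma=sigma,
        lam=lam,
        class_weights=class_weights,
        feature_names=tuple(feature_names),
    )


def _objective(A, y, sw, pen, beta) -> float:
    z = A @ beta
    # log(1+exp(-s z)) with s = +-1 written stably via logaddexp
    nll = sw * (np.logaddexp(0.0, z) - y * z)
    return float(nll.sum() + 0.5 * np.dot(pen * beta, beta))


# --------------------------------------------------------------------------- #
# prediction, aggregation, out-of-fold collection
# --------------------------------------------------------------------------- #


def predict_segment_proba(model: TrainedModel, X: np.ndarray) -> np.ndarray:
    return model.predict_proba(X)


def aggregate_to_side(probs: np.ndarray, groups: np.ndarray) -> pd.Series:
    """Patient-side probability = arithmetic mean of the side's segment probabilities."""
    return pd.Series(np.asarray(probs, dtype=np.float64)).groupby(np.asarray(groups)).mean()


def collect_oof_predictions(
    plan: SplitPlan,
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Out-of-fold segment and side probabilities for every training group.

    Each group is scored exactly once, by the model fitted on the folds that
    exclude it; standardization and class weights are refit per fold.
    Returns one row per segment with columns group, label, proba, fold.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    groups = np.asarray(groups)
    rows = []
    seen: set[str] = set()
    for fold_id, (train_g, val_g) in enumerate(plan.folds):
        if set(val_g) & seen:
            raise AssertionError("group scored by more than one fold")
        seen |= set(val_g)
        tr = np.isin(groups, train_g)
        va = np.isin(groups, val_g)
        model = fit_logistic_l2(X[tr], y[tr], lam=lam)
        proba = model.predict_proba(X[va])
        rows.append(
            pd.DataFrame(
                {"group": groups[va], "label": y[va], "proba": proba, "fold": fold_id}
            )
        )
    out = pd.concat(rows, ignore_index=True)
    if set(out["group"]) != set(plan.train_groups):
        raise AssertionError("out-of-fold predictions do not cover all training groups")
    return out


def side_table(oof: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a segment-level prediction table to patient-side rows."""
    g = oof.groupby("group")
    labels = g["label"].agg(lambda s: _unique_label(s))
    return pd.DataFrame({"proba": g["proba"].mean(), "label": labels})


def _unique_label(s: pd.Series) -> int:
    vals = set(s)
    if len(vals) != 1:
        raise ValueError("inconsistent labels within one patient-side group")
    return int(next(iter(vals)))


# --------------------------------------------------------------------------- #
# operating threshold
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class OperatingThreshold:
    tau: float
    sens_min: float
    sensitivity: float  # achieved on the training OOF predictions
    specificity: float
    from_training_oof: bool = True


def select_threshold(
    probs: np.ndarray, labels: np.ndarray, sens_min: float = 0.90
) -> OperatingThreshold:
    """Lowest threshold with sensitivity >= sens_min; ties -> max specificity.

    Candidates are midpoints between adjacent sorted unique probabilities plus
    boundary sentinels.  A threshold below the minimum probability classifies
    everything positive (sensitivity 1), so the feasible set is never empty.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes required to select a threshold")
    uniq = np.unique(probs)
    cands = np.concatenate([[uniq[0] / 2.0], (uniq[1:] + uniq[:-1]) / 2.0, [(uniq[-1] + 1.0) / 2.0]])
    pos = labels == 1
    best = None
    for tau in cands:
        pred = probs >= tau
        sens = float(pred[pos].mean())
        spec = float((~pred[~pos]).mean())
        if sens >= sens_min:
            # maximize specificity; among equal specificity keep lowest tau
            if best is None or spec > best[1] + 1e-15:
                best = (tau, spec, sens)
    assert best is not None, "feasible set cannot be empty"
    tau, spec, sens = best
    return OperatingThreshold(
        tau=float(tau), sens_min=sens_min, sensitivity=sens, specificity=spec
    )


# --------------------------------------------------------------------------- #
# evaluation
# --------------------------------------------------------------------------- #


@dataclass
class EvalReport:
    auroc: float
    aupr: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    accuracy: float
    confusion: dict[str, int]
    confusion_pct: dict[str, float]
    roc_points: pd.DataFrame = field(repr=False, default=None)
    pr_points: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "confusion": self.confusion,
            "confusion_pct": self.confusion_pct,
        }


def evaluate(probs: np.ndarray, labels: np.ndarray, tau: float) -> EvalReport:
    """Threshold-free (AUROC, AUPR) and thresholded metrics at ``tau``.

    AUROC uses the rank/trapezoid convention (ties count one half); AUPR uses
    step-wise precision-recall integration without linear interpolation.
    """
    probs = np.asarray(probs, dtype=np.float64)
    labels = np.asarray(labels).astype(int)
    if labels.min() == labels.max():
        raise ValueError("AUROC/AUPR undefined for single-class labels")
    auroc = float(roc_auc_score(labels, probs))
    aupr = float(average_precision_score(labels, probs))
    pred = probs >= tau
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    fp = int(np.sum(pred & (labels == 0)))
    n = labels.size
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    prec = tp / (tp + fp) if tp + fp else 0.0
    f1 = 2 * prec * sens / (prec + sens) if prec + sens else 0.0
    acc = (tp + tn) / n
    fpr, tpr, thr = roc_curve(labels, probs)
    p_curve, r_curve, _ = precision_recall_curve(labels, probs)
    return EvalReport(
        auroc=auroc,
        aupr=aupr,
        sensitivity=float(sens),
        specificity=float(spec),
        precision=float(prec),
        f1=float(f1),
        accuracy=float(acc),
        confusion={"tp": tp, "fp": fp, "tn": tn, "fn": fn},
        confusion_pct={k: 100.0 * v / n for k, v in {"tp": tp, "fp": fp, "tn": tn, "fn": fn}.items()},
        roc_points=pd.DataFrame({"fpr": fpr, "tpr": tpr}),
        pr_points=pd.DataFrame({"precision": p_curve, "recall": r_curve}),
    )


# --------------------------------------------------------------------------- #
# full protocol
# --------------------------------------------------------------------------- #


def train_and_evaluate(
    features: pd.DataFrame,
    feature_cols: list[str],
    lam: float = 1.0,
    test_frac: float = 0.15,
    k: int = 5,
    seed: int = 0,
    sens_min: float = 0.90,
) -> dict:
    """End-to-end protocol on a segment-level feature table.

    ``features`` must carry columns ``group_key`` and ``label`` plus the
    feature columns.  Returns the fitted model, split plan, threshold and
    EvalReports at segment and patient-side resolution.
    """
    groups = features["group_key"].to_numpy()
    y = features["label"].to_numpy().astype(int)
    X = features[feature_cols].to_numpy(dtype=np.float64)
    group_labels = {
        g: _unique_label(s) for g, s in features.groupby("group_key")["label"]
    }
    plan = make_split_plan(groups, group_labels, test_frac=test_frac, k=k, seed=seed)
    assert_no_group_leakage(plan)

    tr_mask = np.isin(groups, plan.train_groups)
    te_mask = np.isin(groups, plan.test_groups)

    oof = collect_oof_predictions(plan, X[tr_mask], y[tr_mask], groups[tr_mask], lam=lam)
    oof_sides = side_table(oof)
    threshold = select_threshold(oof_sides["proba"].to_numpy(), oof_sides["label"].to_numpy(), sens_min)

    final = fit_logistic_l2(
        X[tr_mask], y[tr_mask], lam=lam, feature_names=tuple(feature_cols)
    )
    test_proba = final.predict_proba(X[te_mask])
    seg_report = evaluate(test_proba, y[te_mask], threshold.tau)
    sides = side_table(
        pd.DataFrame({"group": groups[te_mask], "label": y[te_mask], "proba": test_proba})
    )
    side_report = evaluate(sides["proba"].to_numpy(), sides["label"].to_numpy(), threshold.tau)
    return {
        "plan": plan,
        "model": final,
        "threshold": threshold,
        "oof": oof,
        "oof_sides": oof_sides,
        "segment_report": seg_report,
        "side_report": side_report,
        "train_mask": tr_mask,
        "test_mask": te_mask,
    }
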