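"""Univariate feature screening under patient-side grouped cross-validation.

Each candidate biomarker is treated as a continuous score for the pathology
label; held-out AUROC and AUPR are computed per grouped fold for the score and
its negation, and the better orientation is retained per metric.  Features are
ranked per metric (rank 1 = best, average ranks on exact ties) and the two
ranks are averaged into a single mean rank.  A classifier-based variant ranks
features by single-feature logistic models over four metrics (AUC, F1, PR-AUC,
accuracy).  As a distributional consistency check, feature values are first
averaged per patient-side group and the two classes compared with a two-sided
Mann-Whitney U test under Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .model import (
    aggregate_to_side,
    fit_logistic_l2,
    side_table,
    stratified_group_kfold,
)


def _rank_descending(scores: pd.Series) -> pd.Series:
    """Rank 1 = best score; exact ties share their average rank; NaN ranks last."""
    filled = scores.fillna(-np.inf)
    return filled.rank(ascending=False, method="average")


def _grouped_folds(groups: np.ndarray, labels: np.ndarray, k: int, seed: int):
    group_label = {}
    for g, y in zip(groups, labels):
        if g in group_label and group_label[g] != y:
            raise ValueError(f"group {g}: inconsistent labels")
        group_label[g] = int(y)
    return stratified_group_kfold(groups, group_label, k, seed)


def univariate_cv_rank(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    k: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Orientation-corrected cross-validated AUROC/AUPR ranking per feature.

    Returns a table indexed by feature with columns cv_auroc, cv_aupr,
    orientation (+1 raw score, -1 negated), rank_auroc, rank_aupr, mean_rank,
    sorted by mean_rank then feature name.
    """
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    folds = _grouped_folds(groups, labels, k, seed)
    records = {}
    for name in features.columns:
        x = features[name].to_numpy(dtype=np.float64)
        per_fold = {"+": {"auroc": [], "aupr": []}, "-": {"auroc": [], "aupr": []}}
        for train_g, val_g in folds:
            va = np.isin(groups, val_g)
            y_va = labels[va]
            if y_va.min() == y_va.max():
                warnings.warn("single-class validation fold skipped", RuntimeWarning)
                continue
            for sign, key in ((1.0, "+"), (-1.0, "-")):
                s = sign * x[va]
                per_fold[key]["auroc"].append(roc_auc_score(y_va, s))
                per_fold[key]["aupr"].append(average_precision_score(y_va, s))
        if np.std(x) == 0 or not per_fold["+"]["auroc"]:
            records[name] = {"cv_auroc": np.nan, "cv_aupr": np.nan, "orientation": 0}
            continue
        mean = {k2: {m: float(np.mean(v)) for m, v in d.items()} for k2, d in per_fold.items()}
        best_auroc = max(mean["+"]["auroc"], mean["-"]["auroc"])
        best_aupr = max(mean["+"]["aupr"], mean["-"]["aupr"])
        orientation = 1 if mean["+"]["auroc"] >= mean["-"]["auroc"] else -1
        records[name] = {
            "cv_auroc": best_auroc,
            "cv_aupr": best_aupr,
            "orientation": orientation,
        }
    table = pd.DataFrame(records).T
    table["rank_auroc"] = _rank_descending(table["cv_auroc"])
    table["rank_aupr"] = _rank_descending(table["cv_aupr"])
    table["mean_rank"] = (table["rank_auroc"] + table["rank_aupr"]) / 2.0
    # deterministic report order: mean rank, then feature name on ties
    return table.sort_index(kind="stable").sort_values("mean_rank", kind="stable")


def baseline_classifier_rank(
    features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    k: int = 5,
    seed: int = 0,
    lam: float = 1.0,
) -> pd.DataFrame:
    """Single-feature logistic ranking over AUC, F1, PR-AUC and accuracy.

    Hyperparameters (regularization, class weights) are held fixed across
    features; the four per-metric ranks are averaged into mean_rank_4metric.
    """
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    folds = _grouped_folds(groups, labels, k, seed)
    records = {}
    for name in features.columns:
        x = features[[name]].to_numpy(dtype=np.float64)
        metrics = {"auc": [], "f1": [], "pr_auc": [], "accuracy": []}
        for train_g, val_g in folds:
            tr = np.isin(groups, train_g)
            va = np.isin(groups, val_g)
            y_va = labels[va]
            if y_va.min() == y_va.max():
                warnings.warn("single-class validation fold skipped", RuntimeWarning)
                continue
            if np.std(x[tr]) == 0:
                continue
            m = fit_logistic_l2(x[tr], labels[tr], lam=lam)
            proba = m.predict_proba(x[va])
            pred = proba >= 0.5
            tp = np.sum(pred & (y_va == 1))
            prec = tp / pred.sum() if pred.sum() else 0.0
            rec = tp / (y_va == 1).sum()
            metrics["auc"].append(roc_auc_score(y_va, proba))
            metrics["pr_auc"].append(average_precision_score(y_va, proba))
            metrics["f1"].append(2 * prec * rec / (prec + rec) if prec + rec else 0.0)
            metrics["accuracy"].append(float(np.mean(pred == (y_va == 1))))
        if not metrics["auc"]:
            records[name] = {m: np.nan for m in metrics}
        else:
            records[name] = {m: float(np.mean(v)) for m, v in metrics.items()}
    table = pd.DataFrame(records).T
    for m in ("auc", "f1", "pr_auc", "accuracy"):
        table[f"rank_{m}"] = _rank_descending(table[m])
    table["mean_rank_4metric"] = table[[f"rank_{m}" for m in ("auc", "f1", "pr_auc", "accuracy")]].mean(axis=1)
    return table.sort_values("mean_rank_4metric", kind="stable")


def aggregate_patient_side(features: pd.DataFrame, groups: np.ndarray) -> pd.DataFrame:
    """One row per patient-side group: mean of its segments' feature values.

    A ``label`` column, if present, must be constant within each group and is
    carried through unchanged.
    """
    groups = np.asarray(groups)
    df = features.copy()
    df["_group"] = groups
    if "label" in df.columns:
        nun = df.groupby("_group")["label"].nunique()
        if (nun > 1).any():
            bad = nun[nun > 1].index.tolist()
            raise ValueError(f"inconsistent labels within groups {bad}")
    agg = df.groupby("_group").mean()
    agg.index.name = "group"
    return agg


def mannwhitney_bh(
    aggregated: pd.DataFrame, labels: np.ndarray, alpha: float = 0.05
) -> pd.DataFrame:
    """Two-sided Mann-Whitney U per feature with BH step-up q-values.

    ``aggregated`` holds one row per patient-side group (see
    :func:`aggregate_patient_side`).  U is the number of (pathological,
    non-pathological) pairs where the pathological value is larger, plus half
    the ties.  Features where either class has fewer than 2 groups are skipped.
    """
    labels = np.asarray(labels).astype(int)
    n1, n0 = int((labels == 1).sum()), int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes required")
    records = {}
    for name in aggregated.columns:
        x = aggregated[name].to_numpy(dtype=np.float64)
        x1, x0 = x[labels == 1], x[labels == 0]
        if x1.size < 2 or x0.size < 2:
            records[name] = {"U": np.nan, "p": np.nan, "n_pos": x1.size, "n_neg": x0.size}
            continue
        res = stats.mannwhitneyu(x1, x0, alternative="two-sided")
        records[name] = {
            "U": float(res.statistic),
            "p": float(res.pvalue),
            "n_pos": x1.size,
            "n_neg": x0.size,
        }
    table = pd.DataFrame(records).T
    table["q"] = bh_qvalues(table["p"].to_numpy())
    table["significant"] = table["q"] <= alpha
    return table


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvals, dtype=np.float64)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    out[ok] = q
    return out


def _grouped_cv_side_auroc(
    X: np.ndarray, labels: np.ndarray, groups: np.ndarray, k: int, seed: int, lam: float
) -> float:
    """OOF patient-side AUROC of a logistic model on the given feature matrix."""
    folds = _grouped_folds(groups, labels, k, seed)
    frames = []
    for train_g, val_g in folds:
        tr = np.isin(groups, train_g)
        va = np.isin(groups, val_g)
        m = fit_logistic_l2(X[tr], labels[tr], lam=lam)
        frames.append(
            pd.DataFrame({"group": groups[va], "label": labels[va], "proba": m.predict_proba(X[va])})
        )
    sides = side_table(pd.concat(frames, ignore_index=True))
    return float(roc_auc_score(sides["label"], sides["proba"]))


def cumulative_subset(
    features_ranked: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    k: int = 5,
    seed: int = 0,
    lam: float = 1.0,
) -> pd.DataFrame:
    """CV patient-side AUROC of the top-1, top-2, ... top-n ranked feature sets.

    ``features_ranked`` columns must already be in rank order (best first).
    """
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    names = list(features_ranked.columns)
    rows = []
    for j in range(1, len(names) + 1):
        X = features_ranked[names[:j]].to_numpy(dtype=np.float64)
        rows.append(
            {"n_features": j, "last_added": names[j - 1],
             "cv_auroc": _grouped_cv_side_auroc(X, labels, groups, k, seed, lam)}
        )
    return pd.DataFrame(rows)


def leave_one_out(
    core_features: pd.DataFrame,
    labels: np.ndarray,
    groups: np.ndarray,
    k: int = 5,
    seed: int = 0,
    lam: float = 1.0,
) -> pd.DataFrame:
    """CV AUROC drop when each core feature is removed from the full set."""
    labels = np.asarray(labels).astype(int)
    groups = np.asarray(groups)
    names = list(core_features.columns)
    full = _grouped_cv_side_auroc(
        core_features.to_numpy(dtype=np.float64), labels, groups, k, seed, lam
    )
    rows = []
    for name in names:
        rest = [n for n in names if n != name]
        auroc = _grouped_cv_side_auroc(
            core_features[rest].to_numpy(dtype=np.float64), labels, groups, k, seed, lam
        )
        rows.append({"removed": name, "cv_auroc": auroc, "delta": full - auroc})
    out = pd.DataFrame(rows)
    out.attrs["full_cv_auroc"] = full
    return out
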