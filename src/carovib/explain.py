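"""Exact additive feature attribution for the final logistic model.

For a linear model on standardized features with independent-feature
(interventional) background, the Shapley value of feature i for one row is
exactly ``phi_i = w_i * (x_i - mu_i)`` on the log-odds scale, with the base
value the model output at the background (the training feature means).  After
standardization the background is the zero vector, so ``phi_i = w_i * x_std_i``
and the base value is the intercept.  Additivity,
``base + sum_i phi_i == logit(p)``, holds to machine precision for every
explained row.  Attributions are reported on the log-odds scale, where the
linear closed form is exact; the sigmoid maps them monotonically to
probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import TrainedModel


@dataclass
class Attribution:
    base_value: float  # log-odds at the background point
    phi: np.ndarray  # [n_rows, n_features] log-odds contributions
    x_std: np.ndarray
    x_raw: np.ndarray
    log_odds: np.ndarray  # predicted log-odds per row
    feature_names: tuple[str, ...]


def linear_shap(model: TrainedModel, X: np.ndarray) -> Attribution:
    """Exact Shapley attributions of the fitted linear model on rows ``X`` (raw scale)."""
    X = np.asarray(X, dtype=np.float64)
    if X.ndim != 2 or X.shape[1] != model.weights.size:
        raise ValueError(f"expected [n, {model.weights.size}] feature matrix, got {X.shape}")
    x_std = model.standardize(X)
    phi = x_std * model.weights[None, :]
    log_odds = model.intercept + phi.sum(axis=1)
    return Attribution(
        base_value=float(model.intercept),
        phi=phi,
        x_std=x_std,
        x_raw=X,
        log_odds=log_odds,
        feature_names=model.feature_names or tuple(f"f{i}" for i in range(model.weights.size)),
    )


def global_importance(attr: Attribution) -> pd.DataFrame:
    """Features ordered by mean |phi|, with a signed-direction summary.

    ``sign_consistency`` is the fraction of rows where the attribution's sign
    matches the standardized feature value's sign (1.0 means larger feature
    values always push the prediction the same way).
    """
    if attr.phi.shape[0] == 0:
        raise ValueError("no attributions to summarize")
    mean_abs = np.abs(attr.phi).mean(axis=0)
    with np.errstate(invalid="ignore"):
        agree = np.sign(attr.phi) == np.sign(attr.x_std)
        nonzero = attr.x_std != 0
        consistency = np.array(
            [
                agree[nonzero[:, j], j].mean() if nonzero[:, j].any() else np.nan
                for j in range(attr.phi.shape[1])
            ]
        )
    table = pd.DataFrame(
        {
            "mean_abs_phi": mean_abs,
            "mean_phi": attr.phi.mean(axis=0),
            "sign_consistency": consistency,
        },
        index=list(attr.feature_names),
    )
    return table.sort_values("mean_abs_phi", ascending=False, kind="stable")
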