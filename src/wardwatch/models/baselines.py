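"""Non-temporal baseline learners on last-day snapshot features.

Thin adapters over scikit-learn and XGBoost for the comparison table:
logistic regression, decision tree, and random forest at library defaults;
gradient boosting at 1000 rounds, eta 0.01, depth 6.  They consume the
(age, sex, final-day filled values, LOS) snapshot vector, since they cannot
represent the time axis.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.ensemble import RandomForestClassifier
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from ..preprocess import NormStats, StayTensor, snapshot_matrix

__all__ = ["SNAPSHOT_BASELINES", "make_baseline", "fit_snapshot_model",
           "score_snapshot_model"]

SNAPSHOT_BASELINES = ("logistic_regression", "decision_tree", "random_forest",
                      "xgboost")


def make_baseline(name: str, seed: int = 0):
    if name == "logistic_regression":
        return LogisticRegression(max_iter=2000)
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "xgboost":
        return XGBClassifier(n_estimators=1000, learning_rate=0.01, max_depth=6,
                             random_state=seed, verbosity=0, eval_metric="logloss")
    raise ValueError(f"unknown baseline {name!r}")


def fit_snapshot_model(name: str, tensors: Sequence[StayTensor],
                       stats: NormStats, seed: int = 0):
    Xs, ys = snapshot_matrix(tensors, stats)
    model = make_baseline(name, seed)
    model.fit(Xs, ys)
    return model


def score_snapshot_model(model, tensors: Sequence[StayTensor],
                         stats: NormStats) -> np.ndarray:
    Xs, _ = snapshot_matrix(tensors, stats)
    return model.predict_proba(Xs)[:, 1]
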