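"""Internal validation: leave-one-out and k-fold cross-validated Q2.

Q2 is the cross-validated analogue of R2: predictions for each compound are
made by a model that never saw it, and

    Q2 = 1 - sum_i (y_i - yhat_(-i))^2 / sum_i (y_i - ybar)^2

where ybar is the mean of *all* observed targets (the dominant QSAR
convention; it also makes k = n fold CV coincide exactly with
leave-one-out). A Q2 well below the training R2 signals overfitting; a Q2
near zero or below means the model predicts no better than the mean.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, LeaveOneOut

from .descriptors import DescriptorMatrix
from .modeling import RegressorSpec, _aligned_targets, default_registry


@dataclass
class CVReport:
    """Cross-validation result with pooled out-of-sample predictions."""

    q2: float
    method: str  # "loo" or "kfold"
    k: int
    seed: int | None
    y_true: np.ndarray
    y_pred: np.ndarray  # out-of-sample prediction per compound, input order
    compound_ids: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"compound_id": self.compound_ids or range(len(self.y_true)),
             "observed": self.y_true, "predicted_oos": self.y_pred}
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"q2": self.q2, "method": self.method, "k": self.k, "seed": self.seed,
             "n": int(len(self.y_true))}, indent=2))


def _design(matrix, targets):
    if isinstance(matrix, DescriptorMatrix):
        return matrix.values, _aligned_targets(matrix, targets), list(matrix.compound_ids)
    X = np.asarray(matrix, dtype=float)
    y = np.asarray(targets, dtype=float)
    return X, y, []


def _q2_from_predictions(y: np.ndarray, y_pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("Q2 undefined: targets are constant")
    return 1.0 - float(np.sum((y - y_pred) ** 2)) / ss_tot


def _cross_validate(X, y, splitter, model_spec: RegressorSpec) -> np.ndarray:
    y_pred = np.full(len(y), np.nan)
    for train_idx, test_idx in splitter.split(X):
        est = model_spec.build()
        est.fit(X[train_idx], y[train_idx])
        y_pred[test_idx] = est.predict(X[test_idx])
    assert not np.isnan(y_pred).any()  # every row predicted exactly once
    return y_pred


def q2_loo(matrix, targets, model_spec: RegressorSpec | None = None) -> CVReport:
    """Leave-one-out Q2: each compound predicted by a model trained on the rest."""
    X, y, ids = _design(matrix, targets)
    if len(y) < 3:
        raise ValueError("leave-one-out needs at least 3 compounds")
    model_spec = model_spec or default_registry()["RFR"]
    y_pred = _cross_validate(X, y, LeaveOneOut(), model_spec)
    return CVReport(q2=_q2_from_predictions(y, y_pred), method="loo", k=len(y),
                    seed=None, y_true=y, y_pred=y_pred, compound_ids=ids)


def q2_kfold(matrix, targets, model_spec: RegressorSpec | None = None,
             k: int = 10, seed: int = 11) -> CVReport:
    """k-fold Q2 from pooled out-of-fold predictions (shuffled, seeded folds)."""
    X, y, ids = _design(matrix, targets)
    if k > len(y):
        raise ValueError(f"k={k} exceeds n={len(y)}")
    model_spec = model_spec or default_registry(seed)["RFR"]
    splitter = KFold(n_splits=k, shuffle=True, random_state=seed)
    y_pred = _cross_validate(X, y, splitter, model_spec)
    return CVReport(q2=_q2_from_predictions(y, y_pred), method="kfold", k=k,
                    seed=seed, y_true=y, y_pred=y_pred, compound_ids=ids)
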