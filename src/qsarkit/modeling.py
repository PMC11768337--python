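"""Regressor registry, benchmarking, persistence and SMILES-level prediction.

The modelling layer treats pIC50 regression as a bake-off: every registered
regressor is fitted on the same train split and scored on train and test
with the standard QSAR metric suite (R2, MAE, SD, RMSE, where SD is the
population standard deviation of the residuals, so RMSE^2 = SD^2 +
mean(residual)^2). Tree ensembles consume raw descriptors; kernel,
Gaussian-process, support-vector and neural regressors are scale-sensitive
and get train-fitted standardization.

The final trained model is persisted as a ModelBundle — a directory with a
diffable JSON metadata file (selected descriptor names, scaler parameters,
seed, split, metrics) next to the serialized estimator — and prediction for
new SMILES recomputes exactly the stored descriptors in stored order.
"""

from __future__ import annotations

import datetime
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import BaggingRegressor, GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.kernel_ridge import KernelRidge
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from . import descriptors as desc_mod
from .chem_data import SplitSpec, pic50_to_ic50, split
from .descriptors import DescriptorMatrix, ScalerParams, apply_scaler, fit_scaler

DEFAULT_SEED = 11


@dataclass(frozen=True)
class RegressorSpec:
    """A named entry in the regressor registry.

    ``scale_required`` marks estimators whose fit depends on feature scale;
    the benchmark standardizes descriptors (train-fitted) only for those.
    """

    name: str
    factory: Callable[..., object]
    scale_required: bool = False
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = DEFAULT_SEED
    takes_seed: bool = True

    def build(self):
        kw = dict(self.hyperparameters)
        if self.takes_seed:
            kw.setdefault("random_state", self.seed)
        est = self.factory(**kw)
        return est

    def resolved_params(self) -> dict:
        """Every hyperparameter as resolved by the library, for provenance."""
        return {k: repr(v) for k, v in self.build().get_params(deep=False).items()}


def default_registry(seed: int = DEFAULT_SEED, include_ann: bool = False) -> dict[str, RegressorSpec]:
    """Library-default regressors with a fixed seed where applicable.

    RFR = random forest, GBR = gradient boosting, KRR = kernel ridge,
    GPR = Gaussian process, BRF = bagging over random forests, SVM = support
    vector regression. The optional ANN entry is a dense 500 -> 5 -> 1
    network (ReLU hidden layers, linear output) trained with batch size 10
    for 100 epochs.
    """
    reg = {
        "RFR": RegressorSpec("RFR", RandomForestRegressor, seed=seed),
        "GBR": RegressorSpec("GBR", GradientBoostingRegressor, seed=seed),
        "KRR": RegressorSpec("KRR", KernelRidge, scale_required=True, takes_seed=False, seed=seed),
        "GPR": RegressorSpec("GPR", GaussianProcessRegressor, scale_required=True, seed=seed),
        "BRF": RegressorSpec(
            "BRF",
            BaggingRegressor,
            hyperparameters={"estimator": RandomForestRegressor(random_state=seed)},
            seed=seed,
        ),
        "SVM": RegressorSpec("SVM", SVR, scale_required=True, takes_seed=False, seed=seed),
    }
    if include_ann:
        reg["ANN"] = RegressorSpec(
            "ANN",
            MLPRegressor,
            scale_required=True,
            hyperparameters={
                "hidden_layer_sizes": (500, 5),
                "activation": "relu",
                "batch_size": 10,
                "max_iter": 100,
            },
            seed=seed,
        )
    return reg


# ---------------------------------------------------------------------------
# metric suite

def metrics(y_true: Sequence[float], y_pred: Sequence[float]) -> dict[str, float]:
    """R2, MAE, SD and RMSE of a prediction vector.

    SD is the population standard deviation of the residuals, so the
    identity RMSE^2 = SD^2 + mean(residual)^2 holds exactly. R2 is
    undefined for constant observations and raises.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("y_true and y_pred must be equal-length and nonempty")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        raise ValueError("R2 undefined: observed values are constant")
    resid = y_true - y_pred
    return {
        "r2": 1.0 - float(np.sum(resid**2)) / ss_tot,
        "mae": float(np.mean(np.abs(resid))),
        "sd": float(np.std(resid, ddof=0)),
        "rmse": float(np.sqrt(np.mean(resid**2))),
    }


def _aligned_targets(matrix: DescriptorMatrix, targets) -> np.ndarray:
    """Targets as an array aligned with matrix rows.

    Accepts an array in row order or a mapping/Series keyed by compound id.
    """
    if isinstance(targets, Mapping):
        return np.array([targets[c] for c in matrix.compound_ids], dtype=float)
    if isinstance(targets, pd.Series):
        return targets.reindex(matrix.compound_ids).to_numpy(dtype=float)
    arr = np.asarray(targets, dtype=float)
    if arr.shape[0] != matrix.shape[0]:
        raise ValueError("targets not aligned with matrix rows")
    return arr


def _scaled_blocks(matrix, train_ids, test_ids, need_scale):
    """Train/test design blocks, standardized on train only when needed."""
    scaler = fit_scaler(matrix, train_ids) if need_scale else None
    m = apply_scaler(matrix, scaler) if scaler is not None else matrix
    return m.rows_for(train_ids), m.rows_for(test_ids), scaler


def benchmark(
    matrix: DescriptorMatrix,
    targets,
    registry: Mapping[str, RegressorSpec] | None = None,
    split_spec: SplitSpec = SplitSpec(),
) -> pd.DataFrame:
    """Fit every registered model on the train split, score train and test.

    Returns one row per model with train/test R2, MAE, SD, RMSE and split
    sizes; a model that fails to fit is recorded as a failed row and the
    run continues. Deterministic for fixed seeds.
    """
    registry = registry or default_registry()
    y = _aligned_targets(matrix, targets)
    y_by_id = dict(zip(matrix.compound_ids, y))
    train_ids, test_ids = split(matrix.compound_ids, split_spec)
    y_train = np.array([y_by_id[c] for c in train_ids])
    y_test = np.array([y_by_id[c] for c in test_ids])

    rows = []
    for name in registry:
        spec = registry[name]
        row: dict = {"model": name, "status": "ok", "n_train": len(train_ids), "n_test": len(test_ids)}
        try:
            X_train, X_test, _ = _scaled_blocks(matrix, train_ids, test_ids, spec.scale_required)
            est = spec.build()
            est.fit(X_train, y_train)
            for part, X, yy in (("train", X_train, y_train), ("test", X_test, y_test)):
                m = metrics(yy, est.predict(X))
                for k, v in m.items():
                    row[f"{k}_{part}"] = v
        except Exception as e:  # failed fits are data, not fatal
            row["status"] = f"failed: {e}"
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# final model persistence and prediction

@dataclass
class ModelBundle:
    """Trained regressor + descriptor names + scaler + provenance.

    The unit of persistence: prediction recomputes exactly the stored
    descriptor names in stored order, applies the stored scaler if present,
    and returns pIC50 with IC50 = 10**(-pIC50) mol/L.
    """

    model: object
    selected_names: list[str]
    scaler: ScalerParams | None
    provenance: dict

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        meta = {
            "selected_names": self.selected_names,
            "scaler": self.scaler.to_dict() if self.scaler else None,
            "provenance": self.provenance,
        }
        (path / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
        joblib.dump(self.model, path / "model.joblib")
        return path

    @classmethod
    def load(cls, path: str | Path) -> "ModelBundle":
        path = Path(path)
        meta = json.loads((path / "metadata.json").read_text())
        return cls(
            model=joblib.load(path / "model.joblib"),
            selected_names=list(meta["selected_names"]),
            scaler=ScalerParams.from_dict(meta["scaler"]) if meta["scaler"] else None,
            provenance=meta["provenance"],
        )


def train_final(
    matrix: DescriptorMatrix,
    targets,
    selected_names: Sequence[str],
    spec: RegressorSpec | None = None,
    split_spec: SplitSpec = SplitSpec(),
) -> ModelBundle:
    """Train the chosen regressor on the selected descriptors and bundle it.

    Fits on the train split, evaluates on train and test, and records seed,
    split, backend, resolved hyperparameters and metrics in provenance.
    """
    spec = spec or default_registry(split_spec.seed)["RFR"]
    missing = [n for n in selected_names if n not in matrix.descriptor_names]
    if missing:
        raise KeyError(f"selected descriptors not in matrix: {missing}")
    sub = matrix.select_columns(selected_names)
    y = _aligned_targets(matrix, targets)
    y_by_id = dict(zip(matrix.compound_ids, y))
    train_ids, test_ids = split(matrix.compound_ids, split_spec)
    X_train, X_test, scaler = _scaled_blocks(sub, train_ids, test_ids, spec.scale_required)
    y_train = np.array([y_by_id[c] for c in train_ids])
    y_test = np.array([y_by_id[c] for c in test_ids])

    est = spec.build()
    est.fit(X_train, y_train)
    prov = {
        "model": spec.name,
        "seed": spec.seed,
        "split": {"test_fraction": split_spec.test_fraction, "seed": split_spec.seed,
                  "n_train": len(train_ids), "n_test": len(test_ids)},
        "backend": matrix.provenance.get("backend", "unknown"),
        "backend_version": matrix.provenance.get("backend_version", ""),
        "hyperparameters": spec.resolved_params(),
        "metrics": {
            "train": metrics(y_train, est.predict(X_train)),
            "test": metrics(y_test, est.predict(X_test)),
        },
        "created": datetime.datetime.now(datetime.timezone.utc).isoformat(),
    }
    return ModelBundle(model=est, selected_names=list(selected_names), scaler=scaler, provenance=prov)


def predict(bundle: ModelBundle, smiles_list: Sequence[str], backend_name: str | None = None) -> pd.DataFrame:
    """pIC50/IC50 predictions for a batch of SMILES.

    Invalid SMILES yield status=error rows without aborting the batch.
    IC50 is reported in mol/L plus a convenience nM column.
    """
    from rdkit import Chem

    backend_name = backend_name or bundle.provenance.get("backend", "rdkit")
    if backend_name not in desc_mod._BACKENDS:
        raise KeyError(f"descriptor backend {backend_name!r} is not registered")
    backend = desc_mod._BACKENDS[backend_name]

    rows = []
    feats, ok_idx = [], []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi) if isinstance(smi, str) else None
        if mol is None:
            rows.append({"smiles": smi, "pic50": np.nan, "ic50_molar": np.nan,
                         "ic50_nM": np.nan, "status": "error: invalid SMILES"})
            continue
        d = backend(mol)
        missing = [n for n in bundle.selected_names if n not in d]
        if missing:
            raise KeyError(f"backend {backend_name!r} does not provide descriptor(s) {missing}")
        vec = np.array([d[n] for n in bundle.selected_names], dtype=float)
        if not np.all(np.isfinite(vec)):
            rows.append({"smiles": smi, "pic50": np.nan, "ic50_molar": np.nan,
                         "ic50_nM": np.nan, "status": "error: descriptor failure"})
            continue
        rows.append(None)  # placeholder, filled after batch prediction
        feats.append(vec)
        ok_idx.append(i)

    if feats:
        X = np.vstack(feats)
        if bundle.scaler is not None:
            X = (X - bundle.scaler.mean) / bundle.scaler.std
        preds = np.asarray(bundle.model.predict(X), dtype=float)
        for i, p in zip(ok_idx, preds):
            ic50 = pic50_to_ic50(float(p))
            rows[i] = {"smiles": smiles_list[i], "pic50": float(p), "ic50_molar": ic50,
                       "ic50_nM": ic50 * 1e9, "status": "ok"}
    return pd.DataFrame(rows)
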