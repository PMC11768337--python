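"""Descriptor-matrix construction, curation and train-fitted scaling.

A descriptor matrix is compounds x named numeric molecular descriptors.
Descriptors come from a pluggable backend (RDKit's full 2D descriptor set
by default); the matrix is then curated by dropping columns that failed for
any compound or are constant across the dataset, and — for scale-sensitive
regressors — standardized with mean/variance fitted on training rows only,
so no information leaks from the test set into preprocessing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
import rdkit
from rdkit import Chem
from rdkit.Chem import Descriptors

MISSING = "MISSING"
CONSTANT = "CONSTANT"

# ---------------------------------------------------------------------------
# backend registry: name -> callable(mol) -> {descriptor_name: float}

_BACKENDS: dict[str, Callable[[Chem.Mol], dict[str, float]]] = {}
_BACKEND_VERSIONS: dict[str, str] = {}


def register_backend(name: str, version: str = "") -> Callable:
    """Decorator registering a descriptor backend under ``name``."""

    def deco(fn: Callable[[Chem.Mol], dict[str, float]]) -> Callable:
        _BACKENDS[name] = fn
        _BACKEND_VERSIONS[name] = version
        return fn

    return deco


def list_backends() -> list[str]:
    return sorted(_BACKENDS)


@register_backend("rdkit", version=rdkit.__version__)
def _rdkit_backend(mol: Chem.Mol) -> dict[str, float]:
    """All of RDKit's 2D descriptors; failures become NaN for later curation."""
    out: dict[str, float] = {}
    for name, fn in Descriptors.descList:
        try:
            v = fn(mol)
            out[name] = float(v) if np.isfinite(v) else float("nan")
        except Exception:
            out[name] = float("nan")
    return out


@dataclass
class DescriptorMatrix:
    """Dense compounds x descriptors matrix with a curation audit trail."""

    compound_ids: list[str]
    descriptor_names: list[str]
    values: np.ndarray  # shape (n, p)
    dropped: list[tuple[str, str]] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.compound_ids) or p != len(self.descriptor_names):
            raise ValueError("matrix shape does not match id/name lengths")
        if len(set(self.descriptor_names)) != p:
            raise ValueError("descriptor names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.compound_ids, columns=self.descriptor_names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.descriptor_names.index(name)]

    def select_columns(self, names: Sequence[str]) -> "DescriptorMatrix":
        idx = [self.descriptor_names.index(n) for n in names]
        return DescriptorMatrix(
            list(self.compound_ids), list(names), self.values[:, idx], provenance=dict(self.provenance)
        )

    def rows_for(self, ids: Sequence[str]) -> np.ndarray:
        pos = {c: i for i, c in enumerate(self.compound_ids)}
        return self.values[[pos[i] for i in ids], :]

    def write_csv(self, path: str | Path, dropped_path: str | Path | None = None) -> None:
        df = self.to_frame()
        df.index.name = "compound_id"
        df.to_csv(path)
        if dropped_path is not None:
            pd.DataFrame(self.dropped, columns=["descriptor", "reason"]).to_csv(dropped_path, index=False)

    @classmethod
    def read_csv(cls, path: str | Path, backend_name: str = "rdkit") -> "DescriptorMatrix":
        """Load a matrix from delimited text.

        The CSV does not carry provenance, so ``backend_name`` declares which
        backend produced (and can reproduce) these columns; the default is
        the built-in RDKit backend.
        """
        df = pd.read_csv(path, index_col=0)
        return cls(
            compound_ids=[str(i) for i in df.index],
            descriptor_names=[str(c) for c in df.columns],
            values=df.to_numpy(dtype=float),
            provenance={"backend": backend_name,
                        "backend_version": _BACKEND_VERSIONS.get(backend_name, "")},
        )


def compute_matrix(records, backend_name: str = "rdkit") -> DescriptorMatrix:
    """One descriptor row per curated compound record.

    Per-descriptor failures are recorded as NaN so :func:`curate_matrix` can
    drop them; the backend name and version are stamped in provenance.
    """
    if backend_name not in _BACKENDS:
        raise KeyError(f"unknown backend {backend_name!r}; registered: {list_backends()}")
    backend = _BACKENDS[backend_name]

    ids, rows = [], []
    names: list[str] | None = None
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles_canonical)
        if mol is None:  # records are curated, but stay defensive
            raise ValueError(f"unparseable curated SMILES for {rec.compound_id}")
        desc = backend(mol)
        if names is None:
            names = list(desc)
        ids.append(rec.compound_id)
        rows.append([desc.get(n, float("nan")) for n in names])
    if names is None:
        raise ValueError("no records supplied")
    return DescriptorMatrix(
        compound_ids=ids,
        descriptor_names=names,
        values=np.array(rows, dtype=float),
        provenance={"backend": backend_name, "backend_version": _BACKEND_VERSIONS.get(backend_name, "")},
    )


def curate_matrix(matrix: DescriptorMatrix) -> DescriptorMatrix:
    """Drop columns with any missing value (MISSING) or zero variance (CONSTANT).

    The dropped log is complete: |kept| + |dropped| = p. Raises if nothing
    survives.
    """
    if matrix.shape[0] < 1:
        raise ValueError("matrix has no rows")
    keep, dropped = [], []
    for j, name in enumerate(matrix.descriptor_names):
        col = matrix.values[:, j]
        if np.isnan(col).any():
            dropped.append((name, MISSING))
        elif np.all(col == col[0]):
            dropped.append((name, CONSTANT))
        else:
            keep.append(j)
    if not keep:
        raise ValueError("all descriptor columns were dropped during curation")
    return DescriptorMatrix(
        compound_ids=list(matrix.compound_ids),
        descriptor_names=[matrix.descriptor_names[j] for j in keep],
        values=matrix.values[:, keep],
        dropped=dropped,
        provenance=dict(matrix.provenance),
    )


@dataclass(frozen=True)
class ScalerParams:
    """Per-descriptor mean and population standard deviation, train-fitted."""

    descriptor_names: tuple[str, ...]
    mean: np.ndarray
    std: np.ndarray

    def to_dict(self) -> dict:
        return {
            "descriptor_names": list(self.descriptor_names),
            "mean": self.mean.tolist(),
            "std": self.std.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScalerParams":
        return cls(
            descriptor_names=tuple(d["descriptor_names"]),
            mean=np.asarray(d["mean"], dtype=float),
            std=np.asarray(d["std"], dtype=float),
        )


def fit_scaler(matrix: DescriptorMatrix, train_ids: Sequence[str]) -> ScalerParams:
    """Fit standardization parameters on training rows only.

    Uses the population (n-denominator) standard deviation, matching the
    fit/transform convention of scikit-learn's StandardScaler. A
    zero-variance training column is an error: it should have been curated.
    """
    train = matrix.rows_for(list(train_ids))
    mean = train.mean(axis=0)
    std = train.std(axis=0, ddof=0)
    if np.any(std == 0):
        bad = [n for n, s in zip(matrix.descriptor_names, std) if s == 0]
        raise ValueError(f"zero-variance training column(s): {bad}")
    return ScalerParams(tuple(matrix.descriptor_names), mean, std)


def apply_scaler(matrix: DescriptorMatrix, params: ScalerParams) -> DescriptorMatrix:
    """Transform all rows with train-fitted parameters: (x - mean) / std."""
    if tuple(matrix.descriptor_names) != params.descriptor_names:
        raise ValueError("scaler was fitted on different descriptor names")
    return DescriptorMatrix(
        compound_ids=list(matrix.compound_ids),
        descriptor_names=list(matrix.descriptor_names),
        values=(matrix.values - params.mean) / params.std,
        dropped=list(matrix.dropped),
        provenance=dict(matrix.provenance),
    )


def invert_scaler(matrix: DescriptorMatrix, params: ScalerParams) -> DescriptorMatrix:
    """Undo :func:`apply_scaler`."""
    if tuple(matrix.descriptor_names) != params.descriptor_names:
        raise ValueError("scaler was fitted on different descriptor names")
    return DescriptorMatrix(
        compound_ids=list(matrix.compound_ids),
        descriptor_names=list(matrix.descriptor_names),
        values=matrix.values * params.std + params.mean,
        dropped=list(matrix.dropped),
        provenance=dict(matrix.provenance),
    )
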