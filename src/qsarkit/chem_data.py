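"""Activity-table ingestion, curation and splitting.

The unit of data in a ligand-based QSAR study is an activity table: one row
per assayed compound carrying a SMILES string and an IC50 (half-maximal
inhibitory concentration). This module canonicalizes structures, collapses
duplicates, applies a potency cutoff, converts between IC50 and pIC50
(= -log10 IC50 in mol/L), and produces reproducible train/test splits.

Internally every concentration is held in mol/L; readers accept nM, uM
(micromolar) and M with an explicit unit, which removes the classic silent
factor-of-1000 unit error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

# machine-readable rejection reasons
INVALID_SMILES = "INVALID_SMILES"
NON_POSITIVE_IC50 = "NON_POSITIVE_IC50"
OVER_CUTOFF = "OVER_CUTOFF"
DUPLICATE = "DUPLICATE"
UNKNOWN_UNIT = "UNKNOWN_UNIT"
MISSING_FIELD = "MISSING_FIELD"

#: multiplicative factor taking a value in the given unit to mol/L
_UNIT_TO_MOLAR = {
    "m": 1.0,
    "mm": 1e-3,
    "um": 1e-6,
    "µm": 1e-6,
    "μm": 1e-6,
    "nm": 1e-9,
    "pm": 1e-12,
}

#: default potency cutoff — keep compounds with IC50 strictly under 10 uM
DEFAULT_CUTOFF_MOLAR = 1e-5


def ic50_to_pic50(ic50_molar: float) -> float:
    """pIC50 = -log10(IC50 / (mol/L)). Raises on non-positive input."""
    if ic50_molar <= 0:
        raise ValueError(f"IC50 must be positive, got {ic50_molar!r}")
    return -math.log10(ic50_molar)


def pic50_to_ic50(pic50: float) -> float:
    """Inverse of :func:`ic50_to_pic50`: IC50 in mol/L = 10**(-pIC50)."""
    return 10.0 ** (-pic50)


def canonical_smiles(smiles: str) -> str | None:
    """RDKit canonical SMILES, or None if the string does not parse."""
    if not isinstance(smiles, str) or not smiles.strip():
        return None
    mol = Chem.MolFromSmiles(smiles.strip())
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


@dataclass(frozen=True)
class CompoundRecord:
    """One curated compound with potency on both scales.

    ``ic50_molar`` is in mol/L and ``pic50 == -log10(ic50_molar)``.
    """

    compound_id: str
    smiles_raw: str
    smiles_canonical: str
    ic50_molar: float
    pic50: float
    source_tag: str | None = None

    def __post_init__(self) -> None:
        if self.ic50_molar <= 0:
            raise ValueError("ic50_molar must be positive")
        if abs(self.pic50 + math.log10(self.ic50_molar)) > 1e-9:
            raise ValueError("pic50 inconsistent with ic50_molar")


@dataclass(frozen=True)
class RejectedRow:
    row: Mapping
    reason: str
    detail: str = ""


@dataclass
class ActivityTable:
    """Curation result: accepted records plus a complete reject log.

    Every input row lands in exactly one of ``records`` / ``rejects``.
    """

    records: list[CompoundRecord]
    rejects: list[RejectedRow] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "compound_id": [r.compound_id for r in self.records],
                "smiles": [r.smiles_canonical for r in self.records],
                "ic50_molar": [r.ic50_molar for r in self.records],
                "pic50": [r.pic50 for r in self.records],
            }
        )

    def rejects_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "smiles": [str(r.row.get("smiles", "")) for r in self.rejects],
                "reason": [r.reason for r in self.rejects],
                "detail": [r.detail for r in self.rejects],
            }
        )

    def write_csv(self, records_path: str | Path, rejects_path: str | Path | None = None) -> None:
        self.to_frame().to_csv(records_path, index=False)
        if rejects_path is not None:
            self.rejects_frame().to_csv(rejects_path, index=False)


def _row_ic50_molar(row: Mapping) -> tuple[float | None, str | None, str]:
    """Extract IC50 in mol/L from a raw row.

    Accepts either ``pic50`` directly or ``ic50`` plus ``unit``.
    Returns (value, reject_reason, detail); value is None on rejection.
    """
    if row.get("pic50") not in (None, ""):
        try:
            pic50 = float(row["pic50"])
        except (TypeError, ValueError):
            return None, MISSING_FIELD, f"unparseable pic50 {row.get('pic50')!r}"
        return pic50_to_ic50(pic50), None, ""
    raw = row.get("ic50")
    if raw in (None, ""):
        return None, MISSING_FIELD, "no ic50 or pic50 value"
    try:
        value = float(raw)
    except (TypeError, ValueError):
        return None, MISSING_FIELD, f"unparseable ic50 {raw!r}"
    if not math.isfinite(value) or value <= 0:
        return None, NON_POSITIVE_IC50, f"ic50={value!r}"
    unit = str(row.get("unit", "M")).strip().lower()
    factor = _UNIT_TO_MOLAR.get(unit)
    if factor is None:
        return None, UNKNOWN_UNIT, f"unit={row.get('unit')!r}"
    return value * factor, None, ""


def curate(
    raw_rows: Iterable[Mapping],
    potency_cutoff_molar: float = DEFAULT_CUTOFF_MOLAR,
) -> ActivityTable:
    """Canonicalize, potency-filter and deduplicate raw activity rows.

    Rules, applied per row in order: the structure must parse (else
    INVALID_SMILES); the potency must be positive with a known unit; the
    IC50 must be strictly below the cutoff (default 10 uM, else OVER_CUTOFF).
    Surviving rows are then collapsed on canonical SMILES: the first
    occurrence becomes the record, later replicates are logged as DUPLICATE.
    Replicate potencies are merged as the median of the pIC50s, which for a
    pair equals the geometric mean of the IC50s — the standard way to pool
    replicate dose-response measurements.
    """
    rows = list(raw_rows)
    if not rows:
        raise ValueError("curate() received an empty input")

    # first pass: per-row validation
    kept: list[tuple[int, Mapping, str, float]] = []  # (idx, row, canon, ic50_molar)
    rejects: list[tuple[int, RejectedRow]] = []
    for i, row in enumerate(rows):
        canon = canonical_smiles(row.get("smiles", ""))
        if canon is None:
            rejects.append((i, RejectedRow(row, INVALID_SMILES)))
            continue
        ic50, reason, detail = _row_ic50_molar(row)
        if reason is not None:
            rejects.append((i, RejectedRow(row, reason, detail)))
            continue
        if not (ic50 < potency_cutoff_molar):
            rejects.append((i, RejectedRow(row, OVER_CUTOFF, f"ic50_molar={ic50:g}")))
            continue
        kept.append((i, row, canon, ic50))

    # second pass: collapse on canonical structure
    groups: dict[str, list[tuple[int, Mapping, float]]] = {}
    for i, row, canon, ic50 in kept:
        groups.setdefault(canon, []).append((i, row, ic50))

    records: list[CompoundRecord] = []
    for canon, members in groups.items():
        first_idx, first_row, _ = members[0]
        pic50 = float(median(ic50_to_pic50(m[2]) for m in members))
        cid = str(first_row.get("compound_id") or f"CMP{first_idx:06d}")
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles_raw=str(first_row.get("smiles", "")),
                smiles_canonical=canon,
                ic50_molar=pic50_to_ic50(pic50),
                pic50=pic50,
                source_tag=first_row.get("source_tag"),
            )
        )
        for i, row, _ in members[1:]:
            rejects.append((i, RejectedRow(row, DUPLICATE, f"merged into {cid}")))

    rejects.sort(key=lambda t: t[0])
    return ActivityTable(records=records, rejects=[r for _, r in rejects])


@dataclass(frozen=True)
class SplitSpec:
    """Shuffle-then-partition train/test split convention.

    A single integer seed drives the shuffle; |test| = round(test_fraction*n).
    """

    test_fraction: float = 0.2
    seed: int = 11

    def __post_init__(self) -> None:
        if not 0.0 < self.test_fraction < 1.0:
            raise ValueError("test_fraction must lie in (0, 1)")


def split(ids: Sequence[str] | ActivityTable, spec: SplitSpec = SplitSpec()) -> tuple[list[str], list[str]]:
    """Deterministic, exhaustive, disjoint train/test partition of ids."""
    if isinstance(ids, ActivityTable):
        ids = ids.ids()
    ids = list(ids)
    n = len(ids)
    if n < 5:
        raise ValueError(f"need at least 5 compounds to split, got {n}")
    n_test = int(round(spec.test_fraction * n))
    n_test = min(max(n_test, 1), n - 1)
    order = np.random.RandomState(spec.seed).permutation(n)
    test = [ids[i] for i in sorted(order[:n_test])]
    train = [ids[i] for i in sorted(order[n_test:])]
    return train, test


# ---------------------------------------------------------------------------
# delimited-text readers

def read_activity_csv(path: str | Path, sep: str = ",") -> list[dict]:
    """Read raw activity rows from delimited text.

    Expected columns: ``smiles`` plus either ``pic50`` or ``ic50`` (with a
    ``unit`` column, or a unit suffix in the header such as ``ic50_nM``).
    Returns raw row dicts ready for :func:`curate`.
    """
    df = pd.read_csv(path, sep=sep)
    df.columns = [c.strip() for c in df.columns]
    cols = {c.lower(): c for c in df.columns}
    if "smiles" not in cols:
        raise ValueError(f"{path}: no 'smiles' column (found {list(df.columns)})")

    ic50_col = unit_suffix = None
    for low, orig in cols.items():
        if low.startswith("ic50_") and low != "ic50_molar":
            ic50_col, unit_suffix = orig, low.split("_", 1)[1]
            break

    rows = []
    for _, r in df.iterrows():
        row: dict = {"smiles": r[cols["smiles"]]}
        if "compound_id" in cols:
            row["compound_id"] = r[cols["compound_id"]]
        if "pic50" in cols:
            row["pic50"] = r[cols["pic50"]]
        elif ic50_col is not None:
            row["ic50"] = r[ic50_col]
            row["unit"] = unit_suffix
        else:
            if "ic50" in cols:
                row["ic50"] = r[cols["ic50"]]
            if "unit" in cols:
                row["unit"] = r[cols["unit"]]
        rows.append(row)
    return rows


def read_smiles_file(path: str | Path) -> list[tuple[str, str]]:
    """Read a SMILES line file (.smi): one ``SMILES [name]`` per line."""
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            name = parts[1].strip() if len(parts) > 1 else f"L{i:06d}"
            out.append((parts[0], name))
    return out
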