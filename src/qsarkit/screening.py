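"""Ligand-based virtual screening: gate by similarity, exclude knowns, rank.

The screen prioritizes candidates from a (possibly very large) SMILES
library in four steps: (1) pick the most potent curated compounds as
references; (2) retain only candidates whose maximum Tanimoto similarity to
any reference reaches the gate threshold (default 0.90) — this doubles as
an applicability-domain filter, keeping predictions close to the training
chemotypes; (3) drop candidates whose canonical structure is already a
known inhibitor; (4) predict pIC50 with the bundled model and return the
top hits by predicted potency. Candidate files stream line by line, so
multi-million-line libraries never need to fit in memory.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .chem_data import ActivityTable, CompoundRecord, canonical_smiles
from .diversity import FingerprintSet, maccs_fingerprints
from .modeling import ModelBundle, predict

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GatedCandidate:
    smiles: str
    name: str
    canonical: str
    max_tanimoto: float
    best_reference: str


def select_references(table: ActivityTable, n: int = 100) -> list[CompoundRecord]:
    """The n most potent records (highest pIC50); ties break on compound_id.

    Asking for more references than the table holds returns everything with
    a warning rather than failing.
    """
    if not table.records:
        raise ValueError("activity table is empty")
    if n > len(table.records):
        logger.warning("requested %d references but table has %d; using all", n, len(table.records))
        n = len(table.records)
    ordered = sorted(table.records, key=lambda r: (-r.pic50, r.compound_id))
    return ordered[:n]


def iter_candidates(path: str | Path) -> Iterator[tuple[str, str]]:
    """Stream (smiles, name) pairs from a .smi file, optionally gzipped."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(None, 1)
            yield parts[0], (parts[1].strip() if len(parts) > 1 else f"L{i:06d}")


def similarity_gate(
    candidates: Iterable[tuple[str, str]] | Sequence[str],
    references: FingerprintSet,
    threshold: float = 0.90,
    log_every: int = 100_000,
) -> list[GatedCandidate]:
    """Retain candidates whose best Tanimoto against the references >= threshold.

    Streams over the candidates; invalid SMILES are logged and skipped. The
    best-matching reference is recorded per survivor.
    """
    from rdkit import Chem
    from rdkit.Chem import MACCSkeys

    ref_bits = references.bits.astype(np.int32)
    ref_counts = ref_bits.sum(axis=1)
    out: list[GatedCandidate] = []
    n_seen = n_bad = 0
    for item in candidates:
        smi, name = item if isinstance(item, tuple) else (item, f"L{n_seen:06d}")
        n_seen += 1
        if log_every and n_seen % log_every == 0:
            logger.info("screened %d candidates, %d retained", n_seen, len(out))
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            n_bad += 1
            logger.debug("invalid candidate SMILES skipped: %r", smi)
            continue
        fp = MACCSkeys.GenMACCSKeys(mol)
        bits = np.zeros(references.bits.shape[1], dtype=np.int32)
        for b in fp.GetOnBits():
            if b > 0:
                bits[b - 1] = 1
        c = bits.sum()
        inter = ref_bits @ bits
        union = ref_counts + c - inter
        sims = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
        best = int(np.argmax(sims))
        if sims[best] >= threshold:
            out.append(
                GatedCandidate(
                    smiles=smi,
                    name=name,
                    canonical=Chem.MolToSmiles(mol),
                    max_tanimoto=float(sims[best]),
                    best_reference=references.compound_ids[best],
                )
            )
    if n_bad:
        logger.info("skipped %d invalid candidate SMILES of %d", n_bad, n_seen)
    return out


def exclude_known(
    gated: Sequence[GatedCandidate], known_smiles: Iterable[str]
) -> tuple[list[GatedCandidate], list[GatedCandidate]]:
    """Split gated candidates into (kept, removed-as-known) by canonical structure."""
    known = set()
    for smi in known_smiles:
        canon = canonical_smiles(smi)
        if canon is not None:
            known.add(canon)
    kept = [g for g in gated if g.canonical not in known]
    removed = [g for g in gated if g.canonical in known]
    return kept, removed


def screen(
    bundle: ModelBundle,
    candidates: Iterable[tuple[str, str]] | Sequence[str] | str | Path,
    references: Sequence[CompoundRecord],
    threshold: float = 0.90,
    top_n: int = 5,
    known_smiles: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Full screen: gate -> exclude knowns -> predict -> rank by pIC50.

    ``known_smiles`` defaults to the references themselves. Returns the top
    hits with similarity audit columns; an empty post-filter set yields an
    empty frame (with a ``status`` attribute in ``DataFrame.attrs``), not an
    error.
    """
    if isinstance(candidates, (str, Path)):
        candidates = iter_candidates(candidates)
    ref_fps = maccs_fingerprints(
        [r.smiles_canonical for r in references], [r.compound_id for r in references]
    )
    gated = similarity_gate(candidates, ref_fps, threshold=threshold)
    known = list(known_smiles) if known_smiles is not None else [r.smiles_canonical for r in references]
    kept, removed = exclude_known(gated, known)

    columns = ["rank", "smiles", "name", "pic50_pred", "ic50_molar", "ic50_nM",
               "max_tanimoto", "best_reference"]
    if not kept:
        empty = pd.DataFrame(columns=columns)
        empty.attrs["status"] = (
            f"no candidates survived the gate/exclusion "
            f"({len(gated)} gated, {len(removed)} removed as known)"
        )
        return empty

    preds = predict(bundle, [g.smiles for g in kept])
    df = pd.DataFrame(
        {
            "smiles": [g.smiles for g in kept],
            "name": [g.name for g in kept],
            "pic50_pred": preds["pic50"].to_numpy(),
            "ic50_molar": preds["ic50_molar"].to_numpy(),
            "ic50_nM": preds["ic50_nM"].to_numpy(),
            "max_tanimoto": [g.max_tanimoto for g in kept],
            "best_reference": [g.best_reference for g in kept],
            "status": preds["status"].to_numpy(),
        }
    )
    df = df[df["status"] == "ok"].drop(columns="status")
    # deterministic order: potency desc, then similarity desc, then name
    df = df.sort_values(["pic50_pred", "max_tanimoto", "name"],
                        ascending=[False, False, True]).reset_index(drop=True)
    df.insert(0, "rank", np.arange(1, len(df) + 1))
    df.attrs["status"] = f"{len(df)} survivors, {len(removed)} removed as known"
    return df.head(top_n).reset_index(drop=True)
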