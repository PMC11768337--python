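"""Fingerprints, Tanimoto similarity and Butina sphere-exclusion clustering.

Dataset diversity is assessed by clustering MACCS-key fingerprints with the
Butina sphere-exclusion algorithm at a fixed Tanimoto *distance* threshold
(distance = 1 - similarity). At the default threshold of 0.3, every member
of a cluster is at least 0.7 similar to its centroid. Many small clusters
mean a diverse library; a few dominant clusters mean redundancy.

The clustering here is a native implementation of sphere exclusion:
neighbor lists are built at distance <= threshold, then the unassigned
compound with the most unassigned neighbors is promoted to centroid and
claims those neighbors, repeatedly, until everything is assigned (singletons
become their own clusters). Ties on neighbor count go to the lower input
index, which makes the output deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import MACCSkeys

MACCS_NBITS = 166  # key 0 of the 167-bit RDKit vector is a placeholder, dropped


@dataclass
class FingerprintSet:
    """Fixed-length binary fingerprints for a list of compounds."""

    compound_ids: list[str]
    bits: np.ndarray  # (n, nbits) bool
    scheme_name: str = "maccs"

    def __post_init__(self) -> None:
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.ndim != 2 or self.bits.shape[0] != len(self.compound_ids):
            raise ValueError("bit matrix shape does not match compound ids")

    def __len__(self) -> int:
        return self.bits.shape[0]

    @property
    def empty_flags(self) -> np.ndarray:
        """True where a fingerprint has no set bit (flagged, still clusterable)."""
        return ~self.bits.any(axis=1)


def maccs_fingerprints(smiles: Sequence[str], ids: Sequence[str] | None = None) -> FingerprintSet:
    """166-bit MACCS key fingerprints for a list of SMILES.

    Raises on unparseable SMILES — fingerprint inputs are expected to be
    curated already.
    """
    if ids is None:
        ids = [f"C{i:06d}" for i in range(len(smiles))]
    rows = []
    for smi in smiles:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            raise ValueError(f"unparseable SMILES for fingerprinting: {smi!r}")
        fp = MACCSkeys.GenMACCSKeys(mol)  # 167 bits, bit 0 unused
        arr = np.zeros(MACCS_NBITS, dtype=bool)
        for b in fp.GetOnBits():
            if b > 0:
                arr[b - 1] = True
        rows.append(arr)
    return FingerprintSet(list(ids), np.array(rows, dtype=bool), "maccs")


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto similarity c / (|a| + |b| - c) of two equal-length bit vectors.

    Two all-zero vectors are defined as identical (1.0) to avoid 0/0.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = int(np.count_nonzero(a | b))
    if union == 0:
        return 1.0
    return int(np.count_nonzero(a & b)) / union


def tanimoto_matrix(fps: FingerprintSet) -> np.ndarray:
    """Dense pairwise Tanimoto similarity; all-zero pairs score 1."""
    x = fps.bits.astype(np.int32)
    counts = x.sum(axis=1)
    inter = x @ x.T
    union = counts[:, None] + counts[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return sim


@dataclass
class Clustering:
    """Butina output: a cluster label per compound plus centroid ids."""

    compound_ids: list[str]
    labels: np.ndarray  # cluster id per compound, 0-based
    centroids: list[str]  # one compound id per cluster, index = cluster id
    distance_threshold: float
    flagged_empty: list[str] = field(default_factory=list)

    def sizes(self) -> np.ndarray:
        return np.bincount(self.labels, minlength=len(self.centroids))

    def to_frame(self) -> pd.DataFrame:
        centroid_set = set(self.centroids)
        return pd.DataFrame(
            {
                "compound_id": self.compound_ids,
                "cluster_id": self.labels,
                "is_centroid": [c in centroid_set for c in self.compound_ids],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def butina_cluster(fps: FingerprintSet, distance_threshold: float = 0.3) -> Clustering:
    """Sphere-exclusion clustering at a Tanimoto distance threshold.

    Repeatedly promotes the unassigned compound with the most unassigned
    neighbors (distance <= threshold) to centroid, assigning those neighbors
    to it; ties break to the lower input index. Every member is therefore
    within the threshold of its centroid, and singletons end up as their own
    clusters.
    """
    n = len(fps)
    if n < 1:
        raise ValueError("need at least one fingerprint")
    if not 0.0 <= distance_threshold <= 1.0:
        raise ValueError("distance_threshold must lie in [0, 1]")

    sim = tanimoto_matrix(fps)
    adj = (1.0 - sim) <= distance_threshold
    np.fill_diagonal(adj, False)

    labels = np.full(n, -1, dtype=int)
    centroids: list[str] = []
    unassigned = np.ones(n, dtype=bool)
    while unassigned.any():
        # count unassigned neighbors of each unassigned compound
        counts = (adj[:, unassigned]).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        cluster_id = len(centroids)
        members = adj[center] & unassigned
        members[center] = True
        labels[members] = cluster_id
        unassigned[members] = False
        centroids.append(fps.compound_ids[center])

    return Clustering(
        compound_ids=list(fps.compound_ids),
        labels=labels,
        centroids=centroids,
        distance_threshold=distance_threshold,
        flagged_empty=[cid for cid, e in zip(fps.compound_ids, fps.empty_flags) if e],
    )


@dataclass
class DiversityReport:
    n_compounds: int
    n_clusters: int
    n_singletons: int
    table: pd.DataFrame  # cluster_id, size, percent — sorted by size descending


def cluster_summary(clustering: Clustering) -> DiversityReport:
    """Cluster-size distribution: counts, percent-of-total (descending), singletons."""
    sizes = clustering.sizes()
    n = len(clustering.compound_ids)
    df = pd.DataFrame({"cluster_id": np.arange(len(sizes)), "size": sizes})
    df["percent"] = 100.0 * df["size"] / n
    df = df.sort_values(["size", "cluster_id"], ascending=[False, True]).reset_index(drop=True)
    return DiversityReport(
        n_compounds=n,
        n_clusters=len(sizes),
        n_singletons=int((sizes == 1).sum()),
        table=df,
    )


def plot_cluster_sizes(report: DiversityReport, path: str | Path) -> None:
    """Bar plot of molecules per cluster (largest first)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(8, 4))
    ax.bar(range(report.n_clusters), report.table["size"])
    ax.set_xlabel("cluster rank")
    ax.set_ylabel("molecules")
    ax.set_title(f"{report.n_clusters} clusters, {report.n_singletons} singletons")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
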