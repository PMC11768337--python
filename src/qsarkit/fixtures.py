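"""Seeded synthetic inputs with known ground truth.

Real inhibitor activity tables are assembled from public bioassay
databases and cannot ship with a toolkit, so every pipeline stage here is
exercised against two tiers of generated data:

* a *planted descriptor matrix* — pure numbers, no chemistry — with a known
  set of informative columns, exact duplicate columns, and a target built
  from the informative columns plus Gaussian noise, so feature selection
  and modelling can be checked against ground truth;
* a *synthetic SMILES library* — generic drug-like scaffolds enumerated
  with small substituents, with activities assigned from a smooth rule on
  computed molecular properties — so the chemistry path (canonicalization,
  descriptors, fingerprints, screening) runs end to end.

Everything is driven by one integer seed and regenerates bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors

from .descriptors import DescriptorMatrix

# ---------------------------------------------------------------------------
# tier 1: planted numeric matrix


@dataclass
class PlantedMatrix:
    """A descriptor matrix whose signal structure is known exactly."""

    matrix: DescriptorMatrix
    targets: pd.Series  # indexed by compound_id
    informative_names: list[str]
    duplicate_map: dict[str, str]  # duplicate column -> source informative column
    noise_sd: float
    seed: int


def make_planted_matrix(
    n: int = 300,
    p: int = 200,
    k: int = 5,
    n_duplicates: int = 10,
    noise_sd: float = 0.3,
    seed: int = 7,
) -> PlantedMatrix:
    """n x p matrix with k informative columns, exact duplicates, and noise.

    The target is a linear combination of the informative columns plus a
    mild pairwise interaction, standardized to unit spread, plus
    Normal(0, noise_sd). Duplicate columns are exact copies of informative
    ones (|r| = 1 with their sources), planted to exercise the correlation
    prune; the remaining columns are independent standard normals.

    The informative columns share a latent factor (pairwise r = 0.5, far
    below the 0.90 prune threshold) while staying marginally standard
    normal. Real descriptor panels are collinear in exactly this way, and
    it gives every informative column strong univariate signal, so a
    single-descriptor ranking can surface the whole family.
    """
    if k + n_duplicates > p:
        raise ValueError("k + n_duplicates must not exceed p")
    if n < 20:
        raise ValueError("need n >= 20 rows")
    rng = np.random.RandomState(seed)

    rho = 0.5  # shared-factor loading: corr(inf_i, inf_j) = rho for i != j
    latent = rng.standard_normal((n, 1))
    informative = np.sqrt(rho) * latent + np.sqrt(1.0 - rho) * rng.standard_normal((n, k))
    inf_names = [f"inf_{i:02d}" for i in range(k)]
    dup_sources = [inf_names[i % k] for i in range(n_duplicates)]
    dup_names = [f"dup_{i:02d}_of_{src}" for i, src in enumerate(dup_sources)]
    duplicates = informative[:, [i % k for i in range(n_duplicates)]]
    n_noise = p - k - n_duplicates
    noise_cols = rng.standard_normal((n, n_noise))
    noise_names = [f"noise_{i:03d}" for i in range(n_noise)]

    values = np.hstack([informative, duplicates, noise_cols])
    names = inf_names + dup_names + noise_names
    ids = [f"S{i:04d}" for i in range(n)]

    weights = 1.0 + rng.rand(k)  # all informative columns matter
    signal = informative @ weights
    if k >= 2:
        signal = signal + 0.5 * informative[:, 0] * informative[:, 1]
    signal = signal / signal.std(ddof=0)
    y = signal + rng.normal(0.0, noise_sd, size=n)

    matrix = DescriptorMatrix(
        compound_ids=ids,
        descriptor_names=names,
        values=values,
        provenance={"backend": "planted", "seed": seed},
    )
    return PlantedMatrix(
        matrix=matrix,
        targets=pd.Series(y, index=ids),
        informative_names=inf_names,
        duplicate_map=dict(zip(dup_names, dup_sources)),
        noise_sd=noise_sd,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# tier 2: synthetic SMILES library

#: generic two-point drug-like scaffolds; {r1}/{r2} are substituent slots
SCAFFOLDS = [
    "O=C(Nc1ccc({r1})cc1)c1ccc({r2})cc1",      # diaryl benzamide
    "c1ccc2nc({r1})c({r2})nc2c1",              # quinoxaline
    "O=C({r1})Nc1ccc2[nH]c({r2})nc2c1",        # benzimidazole amide
    "c1cc({r2})cc(-c2csc({r1})n2)c1",          # aryl thiazole
    "O=C(Nc1ccc({r1})cc1)c1ccc({r2})cn1",      # pyridine amide
    "c1cc({r2})ccc1Oc1ccc({r1})cc1",           # diaryl ether
]

#: r1 substituents are 3-atom chains so a planted near-duplicate can be made
#: by one-carbon homologation (which stays well above a 0.90 MACCS gate)
R1_POOL = ["CCC", "CCO", "CCN"]

R2_POOL = [
    "C", "CC", "CCC", "CO", "CN", "CCO", "CCN", "OC", "OCC", "N", "NC",
    "N(C)C", "F", "Cl", "Br", "C(F)(F)F", "C#N", "C(C)C", "OC(C)C",
    "NCC", "COC", "CNC", "C(=O)N", "C(=O)O", "C(=O)C", "OCCO", "NCCN",
    "CCCC", "CCCO", "SC", "S(C)(=O)=O", "OCCN", "C=C", "CC#N", "CC(C)C",
    "OCC(C)C",
]

#: structurally unrelated small molecules, far below any similarity gate
DECOYS = [
    "CCCCCCCC", "CCO", "CC(C)O", "C1CCCCC1", "CCOCC", "CCCC(=O)O",
    "CC(=O)OC", "OCC(O)CO", "CCCCN", "C1CCOC1",
]

_HOMOLOG = {"CCC": "CCCC", "CCO": "CCCO", "CCN": "CCCN"}


@dataclass
class SyntheticLibrary:
    """Enumerated SMILES with assigned activities plus a screening library."""

    smiles: list[str]
    ids: list[str]
    pic50: np.ndarray
    candidates: list[tuple[str, str]] = field(default_factory=list)  # (smiles, name)
    near_duplicates: list[str] = field(default_factory=list)
    top_active_smiles: str = ""
    seed: int = 0

    def activity_rows(self) -> list[dict]:
        """Raw rows in the dialect the curation stage consumes."""
        return [
            {"compound_id": cid, "smiles": smi, "pic50": float(p)}
            for cid, smi, p in zip(self.ids, self.smiles, self.pic50)
        ]

    def write_smi(self, path, which: str = "candidates") -> None:
        items = self.candidates if which == "candidates" else list(zip(self.smiles, self.ids))
        with open(path, "w") as fh:
            for smi, name in items:
                fh.write(f"{smi} {name}\n")


def _property_activity(mols: list[Chem.Mol], rng: np.random.RandomState, noise_sd: float) -> np.ndarray:
    """Smooth activity rule on cheap molecular properties, mapped into [5, 10].

    Potency increases with lipophilicity and H-bonding capacity and
    decreases with excessive polar surface area — a caricature of real
    potency trends, chosen only so that activity is a learnable function of
    computed descriptors.
    """
    props = np.array(
        [
            [
                Crippen.MolLogP(m),
                Descriptors.TPSA(m),
                Descriptors.NumHDonors(m),
                Descriptors.NumHAcceptors(m),
                Descriptors.MolWt(m),
            ]
            for m in mols
        ]
    )
    z = (props - props.mean(axis=0)) / np.where(props.std(axis=0) > 0, props.std(axis=0), 1.0)
    raw = 1.2 * z[:, 0] - 0.8 * z[:, 1] + 0.6 * z[:, 2] + 0.7 * z[:, 3] + 0.4 * z[:, 4]
    raw = raw + 0.3 * z[:, 0] * z[:, 3]  # mild interaction
    lo, hi = raw.min(), raw.max()
    scaled = 5.2 + 4.5 * (raw - lo) / (hi - lo)
    return np.clip(scaled + rng.normal(0.0, noise_sd, size=len(mols)), 5.0, 10.0)


def make_synthetic_library(
    n_scaffolds: int = 4,
    n_variants: int = 100,
    seed: int = 7,
    noise_sd: float = 0.15,
    n_decoys: int = 10,
) -> SyntheticLibrary:
    """Enumerate ~n_scaffolds * n_variants valid SMILES with activities.

    Activities come from a deterministic property rule plus Normal(0,
    noise_sd) noise (0.15 log units, at the low end of inter-assay
    reproducibility) and lie in [5, 10], mirroring a curated potency
    regime. The screening candidate list holds one planted one-carbon
    homolog of the top active (novel, but far above a 0.90 MACCS gate),
    ``n_decoys`` structurally unrelated molecules far below any gate, and
    the reference compounds themselves.
    """
    if not 1 <= n_scaffolds <= len(SCAFFOLDS):
        raise ValueError(f"n_scaffolds must be in [1, {len(SCAFFOLDS)}]")
    rng = np.random.RandomState(seed)

    smiles: list[str] = []
    subst: list[tuple[int, str, str]] = []  # (scaffold index, r1, r2)
    seen: set[str] = set()
    for s_idx in range(n_scaffolds):
        combos = [(r1, r2) for r1 in R1_POOL for r2 in R2_POOL]
        order = rng.permutation(len(combos))
        taken = 0
        for ci in order:
            if taken >= n_variants:
                break
            r1, r2 = combos[ci]
            smi = SCAFFOLDS[s_idx].format(r1=r1, r2=r2)
            mol = Chem.MolFromSmiles(smi)
            if mol is None:
                continue
            canon = Chem.MolToSmiles(mol)
            if canon in seen:
                continue
            seen.add(canon)
            smiles.append(canon)
            subst.append((s_idx, r1, r2))
            taken += 1

    mols = [Chem.MolFromSmiles(s) for s in smiles]
    pic50 = _property_activity(mols, rng, noise_sd)
    ids = [f"SYN{i:04d}" for i in range(len(smiles))]

    # plant a near-duplicate of the top active: homologate its r1 chain
    top = int(np.argmax(pic50))
    s_idx, r1, r2 = subst[top]
    near_smi = Chem.MolToSmiles(
        Chem.MolFromSmiles(SCAFFOLDS[s_idx].format(r1=_HOMOLOG[r1], r2=r2))
    )
    assert near_smi not in seen, "planted near-duplicate collided with the library"

    candidates = [(near_smi, "near_dup_top")]
    candidates += [(d, f"decoy_{i:02d}") for i, d in enumerate(DECOYS[:n_decoys])]
    candidates += [(s, f"lib_{cid}") for s, cid in zip(smiles, ids)]

    return SyntheticLibrary(
        smiles=smiles,
        ids=ids,
        pic50=pic50,
        candidates=candidates,
        near_duplicates=[near_smi],
        top_active_smiles=smiles[top],
        seed=seed,
    )
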