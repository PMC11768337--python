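"""Two-stage descriptor selection with a correlation prune.

Stage 1 ranks every descriptor by the test-set R2 of a regressor trained on
that single column (univariate screening against held-out data rather than
a correlation coefficient, so nonlinear single-descriptor relationships are
credited). Stage 2 walks the top of the ranking in order and greedily grows
the model: a candidate is skipped if its absolute Pearson correlation with
any already-included descriptor reaches the prune threshold (default 0.90,
computed on training rows only so the decision never sees test data);
otherwise it is included, the model is refitted, and the test R2 is appended
to the R2-vs-k curve. The number of descriptors k is then chosen as the
smallest k whose R2 is within epsilon of the curve maximum (the plateau).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .chem_data import SplitSpec, split
from .descriptors import DescriptorMatrix
from .modeling import RegressorSpec, _aligned_targets, default_registry, metrics


@dataclass
class SelectionTrace:
    """Full audit of a greedy selection run."""

    ranked: pd.DataFrame  # descriptor, r2_test — univariate ranking, descending
    included_names: list[str]  # in inclusion order
    skipped: list[tuple[str, str, float]]  # (name, blocking_name, |r|)
    curve: list[tuple[int, float]]  # (k, R2_test) per successful inclusion
    chosen_k: int | None = None
    params: dict = field(default_factory=dict)

    def curve_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.curve, columns=["k", "r2_test"])

    def selected(self) -> list[str]:
        """The first chosen_k included descriptors (all if chosen_k unset)."""
        k = self.chosen_k if self.chosen_k is not None else len(self.included_names)
        return self.included_names[:k]

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ranked": self.ranked.to_dict(orient="records"),
            "included_names": self.included_names,
            "skipped": [{"name": n, "blocking_name": b, "abs_r": r} for n, b, r in self.skipped],
            "curve": [{"k": k, "r2_test": v} for k, v in self.curve],
            "chosen_k": self.chosen_k,
            "params": self.params,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SelectionTrace":
        d = json.loads(Path(path).read_text())
        return cls(
            ranked=pd.DataFrame(d["ranked"]),
            included_names=list(d["included_names"]),
            skipped=[(s["name"], s["blocking_name"], s["abs_r"]) for s in d["skipped"]],
            curve=[(c["k"], c["r2_test"]) for c in d["curve"]],
            chosen_k=d["chosen_k"],
            params=d.get("params", {}),
        )


def _split_blocks(matrix: DescriptorMatrix, targets, split_spec: SplitSpec):
    y = _aligned_targets(matrix, targets)
    y_by_id = dict(zip(matrix.compound_ids, y))
    train_ids, test_ids = split(matrix.compound_ids, split_spec)
    pos = {c: i for i, c in enumerate(matrix.compound_ids)}
    tr = np.array([pos[c] for c in train_ids])
    te = np.array([pos[c] for c in test_ids])
    return tr, te, np.array([y_by_id[c] for c in train_ids]), np.array([y_by_id[c] for c in test_ids])


def rank_univariate(
    matrix: DescriptorMatrix,
    targets,
    split_spec: SplitSpec = SplitSpec(),
    model_spec: RegressorSpec | None = None,
) -> pd.DataFrame:
    """Rank descriptors by single-column test R2, descending.

    One model per descriptor: fit on the train block of that column alone,
    score R2 on the test block. Deterministic at a fixed seed.
    """
    model_spec = model_spec or default_registry(split_spec.seed)["RFR"]
    tr, te, y_train, y_test = _split_blocks(matrix, targets, split_spec)
    scores = []
    for j, name in enumerate(matrix.descriptor_names):
        col = matrix.values[:, j]
        est = model_spec.build()
        est.fit(col[tr, None], y_train)
        scores.append((name, metrics(y_test, est.predict(col[te, None]))["r2"]))
    df = pd.DataFrame(scores, columns=["descriptor", "r2_test"])
    # stable mergesort keeps input column order among exact ties
    return df.sort_values("r2_test", ascending=False, kind="mergesort").reset_index(drop=True)


def greedy_select(
    ranked: pd.DataFrame,
    matrix: DescriptorMatrix,
    targets,
    split_spec: SplitSpec = SplitSpec(),
    top_pool: int = 100,
    corr_threshold: float = 0.90,
    max_k: int | None = None,
    model_spec: RegressorSpec | None = None,
    epsilon: float = 0.001,
) -> SelectionTrace:
    """Greedy rank-order inclusion with an |r| >= threshold correlation prune.

    Visits the top ``top_pool`` ranked descriptors in order. A candidate
    whose train-set |Pearson r| with any included descriptor reaches
    ``corr_threshold`` is skipped and logged with the blocking name;
    otherwise it is included and the model refitted (same seed each time),
    appending (k, R2_test) to the curve. Stops at ``max_k`` inclusions or
    pool exhaustion, then applies the plateau rule to set ``chosen_k``.
    """
    if ranked.empty:
        raise ValueError("ranked descriptor list is empty")
    if max_k is not None and max_k < 1:
        raise ValueError("max_k must be >= 1")
    model_spec = model_spec or default_registry(split_spec.seed)["RFR"]
    tr, te, y_train, y_test = _split_blocks(matrix, targets, split_spec)
    name_to_col = {n: j for j, n in enumerate(matrix.descriptor_names)}

    pool = [n for n in ranked["descriptor"].tolist() if n in name_to_col][:top_pool]
    included: list[str] = []
    included_train: list[np.ndarray] = []
    skipped: list[tuple[str, str, float]] = []
    curve: list[tuple[int, float]] = []

    for name in pool:
        col = matrix.values[:, name_to_col[name]]
        col_tr = col[tr]
        # correlation prune against every included descriptor, train rows only
        blocker = None
        for inc_name, inc_tr in zip(included, included_train):
            r = abs(float(np.corrcoef(col_tr, inc_tr)[0, 1]))
            if np.isnan(r):
                r = 0.0
            if r >= corr_threshold:
                blocker = (inc_name, r)
                break
        if blocker is not None:
            skipped.append((name, blocker[0], blocker[1]))
            continue
        included.append(name)
        included_train.append(col_tr)
        cols = [name_to_col[n] for n in included]
        est = model_spec.build()
        est.fit(matrix.values[np.ix_(tr, cols)], y_train)
        r2 = metrics(y_test, est.predict(matrix.values[np.ix_(te, cols)]))["r2"]
        curve.append((len(included), r2))
        if max_k is not None and len(included) >= max_k:
            break

    trace = SelectionTrace(
        ranked=ranked,
        included_names=included,
        skipped=skipped,
        curve=curve,
        params={
            "top_pool": top_pool,
            "corr_threshold": corr_threshold,
            "max_k": max_k,
            "epsilon": epsilon,
            "seed": split_spec.seed,
            "model": model_spec.name,
        },
    )
    trace.chosen_k = choose_k(curve, epsilon=epsilon)
    return trace


def choose_k(curve: Sequence[tuple[int, float]], epsilon: float = 0.001, override: int | None = None) -> int:
    """Smallest k whose R2 is within epsilon of the curve maximum.

    ``override`` forces an explicit k (for by-inspection choices).
    """
    if not curve:
        raise ValueError("empty R2 curve")
    if override is not None:
        return override
    best = max(v for _, v in curve)
    for k, v in curve:
        if v >= best - epsilon:
            return k
    return curve[-1][0]  # unreachable: the max itself satisfies the bound


def plot_curve(trace: SelectionTrace, path: str | Path) -> None:
    """R2-vs-number-of-descriptors line plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = trace.curve_frame()
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.plot(df["k"], df["r2_test"], marker="o", ms=3)
    if trace.chosen_k is not None:
        ax.axvline(trace.chosen_k, color="red", ls="--", lw=1, label=f"chosen k = {trace.chosen_k}")
        ax.legend()
    ax.set_xlabel("number of descriptors")
    ax.set_ylabel("R2 (test)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
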