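"""Independent reference implementations used only to check the package.

These deliberately avoid the package's own code paths: similarity is
computed on Python sets of on-bit indices, and clustering is a literal,
O(n^3) restatement of sphere exclusion that recounts neighbors from
scratch every round.
"""

from __future__ import annotations

import numpy as np


def tanimoto_sets(a: set[int], b: set[int]) -> float:
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def butina_bruteforce(bits: np.ndarray, distance_threshold: float) -> list[int]:
    """Sphere-exclusion cluster labels by exhaustive recounting.

    Each round: for every unassigned compound, count its unassigned
    neighbors at distance <= threshold; promote the one with the most
    (lowest index on ties) to centroid of a new cluster containing itself
    and those neighbors. Repeat until all are assigned.
    """
    onbits = [set(np.flatnonzero(row)) for row in np.asarray(bits, dtype=bool)]
    n = len(onbits)
    labels = [-1] * n
    next_cluster = 0
    while any(l == -1 for l in labels):
        best_i, best_count = -1, -1
        for i in range(n):
            if labels[i] != -1:
                continue
            count = sum(
                1
                for j in range(n)
                if j != i
                and labels[j] == -1
                and (1.0 - tanimoto_sets(onbits[i], onbits[j])) <= distance_threshold
            )
            if count > best_count:  # strict: ties keep the lower index
                best_i, best_count = i, count
        labels[best_i] = next_cluster
        for j in range(n):
            if (
                j != best_i
                and labels[j] == -1
                and (1.0 - tanimoto_sets(onbits[best_i], onbits[j])) <= distance_threshold
            ):
                labels[j] = next_cluster
        next_cluster += 1
    return labels


def q2_loo_mean_only(y: np.ndarray) -> float:
    """Brute-force leave-one-out Q2 of the predict-the-mean model."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    press = 0.0
    for i in range(n):
        rest = np.delete(y, i)
        press += (y[i] - rest.mean()) ** 2
    return 1.0 - press / np.sum((y - y.mean()) ** 2)
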