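import numpy as np
import pytest

import qsarkit as qk
from qsarkit.chem_data import SplitSpec


@pytest.fixture(scope="session")
def small_library():
    """~80-compound synthetic library shared by the chemistry-path tests."""
    return qk.make_synthetic_library(n_scaffolds=2, n_variants=40, seed=7)


@pytest.fixture(scope="session")
def small_table(small_library):
    return qk.curate(small_library.activity_rows())


@pytest.fixture(scope="session")
def small_matrix(small_table):
    return qk.curate_matrix(qk.compute_matrix(small_table.records))


@pytest.fixture(scope="session")
def small_targets(small_table):
    return {r.compound_id: r.pic50 for r in small_table.records}


@pytest.fixture(scope="session")
def split_spec():
    return SplitSpec(test_fraction=0.2, seed=11)


@pytest.fixture(scope="session")
def trained_bundle(small_matrix, small_targets, split_spec):
    """Final model on a compact selected set, shared by persistence/screening tests."""
    ranked = qk.rank_univariate(small_matrix, small_targets, split_spec)
    trace = qk.greedy_select(ranked, small_matrix, small_targets, split_spec,
                             top_pool=40, max_k=10)
    return qk.train_final(small_matrix, small_targets, trace.selected(),
                          split_spec=split_spec), trace


def random_fingerprints(n: int, nbits: int, density: float, seed: int) -> np.ndarray:
    rng = np.random.RandomState(seed)
    return rng.rand(n, nbits) < density
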