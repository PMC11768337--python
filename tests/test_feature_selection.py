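import numpy as np
import pytest

from qsarkit import feature_selection as fs
from qsarkit.chem_data import SplitSpec
from qsarkit.descriptors import DescriptorMatrix
from qsarkit.fixtures import make_planted_matrix
from qsarkit.modeling import _aligned_targets


@pytest.fixture(scope="module")
def planted():
    # 3 informative of 40 columns, 4 exact duplicates, mild noise
    return make_planted_matrix(n=120, p=40, k=3, n_duplicates=4, noise_sd=0.2, seed=7)


@pytest.fixture(scope="module")
def spec():
    return SplitSpec(0.2, 11)


@pytest.fixture(scope="module")
def ranked(planted, spec):
    return fs.rank_univariate(planted.matrix, planted.targets, spec)


class TestRankUnivariate:
    def test_leaked_target_column_ranked_first(self, planted, spec):
        m, y = planted.matrix, planted.targets
        leaky = DescriptorMatrix(
            list(m.compound_ids),
            m.descriptor_names + ["leak"],
            np.hstack([m.values, _aligned_targets(m, y)[:, None]]),
        )
        ranked = fs.rank_univariate(leaky, y, spec)
        assert ranked["descriptor"].iloc[0] == "leak"
        assert ranked["r2_test"].iloc[0] > 0.9

    def test_informative_beat_noise(self, planted, ranked):
        top = set(ranked["descriptor"].head(10))
        hits = sum(1 for n in planted.informative_names if n in top)
        assert hits >= 2  # duplicates of informative columns also rank high

    def test_noise_columns_score_low(self, ranked):
        noise_scores = ranked[ranked["descriptor"].str.startswith("noise_")]["r2_test"]
        assert noise_scores.max() < 0.2

    def test_deterministic(self, planted, spec, ranked):
        again = fs.rank_univariate(planted.matrix, planted.targets, spec)
        assert again.equals(ranked)


class TestGreedySelect:
    def test_exact_duplicate_skipped_with_blocking_name(self, planted, ranked, spec):
        trace = fs.greedy_select(ranked, planted.matrix, planted.targets, spec,
                                 top_pool=40, max_k=15)
        # identity groups: each informative column plus its exact copies
        groups: dict[str, set[str]] = {n: {n} for n in planted.informative_names}
        for dup, src in planted.duplicate_map.items():
            groups[src].add(dup)
        included = set(trace.included_names)
        skip_log = {name: (blocker, r) for name, blocker, r in trace.skipped}
        for members in groups.values():
            # exactly one of each identical family gets in; the rest are
            # skipped at |r| = 1 with a family member named as the blocker
            assert len(members & included) == 1
            for name in members - included:
                assert name in skip_log
                blocker, r = skip_log[name]
                assert blocker in members
                assert r == pytest.approx(1.0)

    def test_no_included_pair_above_threshold(self, planted, ranked, spec):
        trace = fs.greedy_select(ranked, planted.matrix, planted.targets, spec,
                                 top_pool=40, max_k=15)
        train_ids, _ = __import__("qsarkit").split(planted.matrix.compound_ids, spec)
        block = planted.matrix.select_columns(trace.included_names).rows_for(train_ids)
        corr = np.corrcoef(block.T)
        off = np.abs(corr[~np.eye(len(trace.included_names), dtype=bool)])
        assert off.max() < 0.90

    def test_orthogonal_columns_none_skipped(self, spec):
        rng = np.random.RandomState(0)
        q, _ = np.linalg.qr(rng.standard_normal((60, 6)))
        m = DescriptorMatrix([f"C{i}" for i in range(60)],
                             [f"f{j}" for j in range(6)], q)
        y = q @ np.arange(1, 7)
        ranked = fs.rank_univariate(m, y, spec)
        trace = fs.greedy_select(ranked, m, y, spec, top_pool=6)
        assert not trace.skipped
        assert len(trace.curve) == 6

    def test_visit_accounting(self, planted, ranked, spec):
        trace = fs.greedy_select(ranked, planted.matrix, planted.targets, spec,
                                 top_pool=30)
        assert len(trace.included_names) + len(trace.skipped) == 30

    def test_corrupting_test_targets_leaves_inclusions_unchanged(self, planted, ranked, spec):
        import qsarkit

        y = planted.targets.copy()
        train_ids, test_ids = qsarkit.split(planted.matrix.compound_ids, spec)
        y_bad = y.copy()
        y_bad.loc[test_ids] = y.loc[test_ids].sample(frac=1.0, random_state=3).to_numpy()
        a = fs.greedy_select(ranked, planted.matrix, y, spec, top_pool=20, max_k=10)
        b = fs.greedy_select(ranked, planted.matrix, y_bad, spec, top_pool=20, max_k=10)
        # test-side corruption changes the curve but not the train-side decisions
        assert a.included_names == b.included_names
        assert a.skipped == b.skipped

    def test_bad_max_k_is_error(self, planted, ranked, spec):
        with pytest.raises(ValueError):
            fs.greedy_select(ranked, planted.matrix, planted.targets, spec, max_k=0)

    def test_trace_json_round_trip(self, tmp_path, planted, ranked, spec):
        trace = fs.greedy_select(ranked, planted.matrix, planted.targets, spec,
                                 top_pool=20, max_k=8)
        trace.to_json(tmp_path / "trace.json")
        back = fs.SelectionTrace.from_json(tmp_path / "trace.json")
        assert back.included_names == trace.included_names
        assert back.curve == trace.curve
        assert back.chosen_k == trace.chosen_k


class TestChooseK:
    def test_strictly_increasing_curve_takes_last(self):
        curve = [(1, 0.5), (2, 0.6), (3, 0.7)]
        assert fs.choose_k(curve) == 3

    def test_flat_after_plateau(self):
        curve = [(1, 0.5), (3, 0.8), (5, 0.9), (7, 0.9005), (9, 0.8998)]
        assert fs.choose_k(curve, epsilon=0.001) == 5

    def test_published_curve_anchors(self):
        # the 5-descriptor model scores 0.893, nine reach 0.930, 41 plateau at 0.941
        curve = [(1, 0.893), (9, 0.930), (41, 0.941)]
        assert fs.choose_k(curve, epsilon=0.001) == 41

    def test_override(self):
        assert fs.choose_k([(1, 0.1), (2, 0.9)], override=1) == 1

    def test_empty_curve_error(self):
        with pytest.raises(ValueError):
            fs.choose_k([])


class TestRecovery:
    def test_planted_recovery_within_tolerance(self, planted, ranked, spec):
        """Selected set predicts nearly as well as the true informative set."""
        import qsarkit
        from qsarkit.modeling import default_registry, metrics

        trace = fs.greedy_select(ranked, planted.matrix, planted.targets, spec,
                                 top_pool=40, max_k=15)
        train_ids, test_ids = qsarkit.split(planted.matrix.compound_ids, spec)
        y = planted.targets

        def r2_for(names):
            sub = planted.matrix.select_columns(names)
            est = default_registry()["RFR"].build()
            est.fit(sub.rows_for(train_ids), y.loc[train_ids])
            return metrics(y.loc[test_ids], est.predict(sub.rows_for(test_ids)))["r2"]

        assert r2_for(trace.selected()) >= r2_for(planted.informative_names) - 0.05
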