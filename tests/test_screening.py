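import numpy as np
import pytest

import qsarkit as qk
from qsarkit import screening as sc
from qsarkit.chem_data import curate
from qsarkit.diversity import FingerprintSet


def bitset(on, nbits=32):
    v = np.zeros(nbits, dtype=bool)
    v[list(on)] = True
    return v


class TestSelectReferences:
    def make_table(self, pic50s):
        rows = [dict(compound_id=f"C{i}", smiles="C" * (i + 1) + "O", pic50=p)
                for i, p in enumerate(pic50s)]
        return curate(rows)

    def test_top_n_by_potency(self):
        table = self.make_table([9.1, 8.0, 7.5, 6.0])
        refs = sc.select_references(table, n=3)
        assert [r.pic50 for r in refs] == [9.1, 8.0, 7.5]

    def test_tie_breaks_on_id(self):
        rows = [dict(compound_id="B", smiles="CCO", pic50=8.0),
                dict(compound_id="A", smiles="CCN", pic50=8.0),
                dict(compound_id="C", smiles="CCC(N)=O", pic50=7.0)]
        refs = sc.select_references(curate(rows), n=1)
        assert refs[0].compound_id == "A"

    def test_oversized_request_returns_all(self, caplog):
        table = self.make_table([7.0, 6.5])
        with caplog.at_level("WARNING"):
            refs = sc.select_references(table, n=100)
        assert len(refs) == 2
        assert any("using all" in r.message for r in caplog.records)

    def test_empty_table_error(self):
        table = self.make_table([7.0])
        table.records = []
        with pytest.raises(ValueError):
            sc.select_references(table)


class TestSimilarityGate:
    def refs(self):
        return FingerprintSet(["R0", "R1"],
                              np.array([bitset(range(10)), bitset(range(20, 28))]))

    def test_crafted_9_of_10_bits_below_gate(self, monkeypatch):
        """Candidate sharing 9 of 10 reference bits plus 2 extra: T = 9/11 < 0.9."""
        from qsarkit import diversity as dv

        cand = bitset(set(range(9)) | {30}, nbits=166)
        ref = FingerprintSet(["R0"], bitset(range(10), nbits=166)[None, :])
        t = dv.tanimoto(cand, ref.bits[0])
        assert t == pytest.approx(9 / 11)
        assert t < 0.90

    def test_identical_candidate_retained_at_1(self, small_table, trained_bundle):
        refs = sc.select_references(small_table, n=5)
        from qsarkit.diversity import maccs_fingerprints

        fps = maccs_fingerprints([r.smiles_canonical for r in refs],
                                 [r.compound_id for r in refs])
        gated = sc.similarity_gate([(refs[0].smiles_canonical, "same")], fps, threshold=0.90)
        assert len(gated) == 1
        assert gated[0].max_tanimoto == pytest.approx(1.0)
        assert gated[0].best_reference == refs[0].compound_id

    def test_dissimilar_candidates_dropped_and_invalid_skipped(self, small_table):
        refs = sc.select_references(small_table, n=5)
        from qsarkit.diversity import maccs_fingerprints

        fps = maccs_fingerprints([r.smiles_canonical for r in refs])
        gated = sc.similarity_gate([("CCCCCCCC", "decoy"), ("C1CC", "bad")], fps, 0.90)
        assert gated == []

    @pytest.mark.parametrize("seed", range(3))
    def test_gate_monotonicity(self, seed, small_table, small_library):
        refs = sc.select_references(small_table, n=10)
        from qsarkit.diversity import maccs_fingerprints

        fps = maccs_fingerprints([r.smiles_canonical for r in refs],
                                 [r.compound_id for r in refs])
        rng = np.random.RandomState(seed)
        cands = [(s, f"c{i}") for i, s in enumerate(
            rng.choice(small_library.smiles, size=20, replace=False))]
        lo = {g.name for g in sc.similarity_gate(cands, fps, 0.80)}
        hi = {g.name for g in sc.similarity_gate(cands, fps, 0.95)}
        assert hi <= lo


class TestExcludeKnown:
    def test_known_removed_and_accounting(self, small_table):
        refs = sc.select_references(small_table, n=5)
        from qsarkit.diversity import maccs_fingerprints

        fps = maccs_fingerprints([r.smiles_canonical for r in refs],
                                 [r.compound_id for r in refs])
        cands = [(r.smiles_canonical, f"k{i}") for i, r in enumerate(refs[:3])]
        gated = sc.similarity_gate(cands, fps, 0.90)
        kept, removed = sc.exclude_known(gated, [r.smiles_canonical for r in refs])
        assert kept == []
        assert len(kept) + len(removed) == len(gated) == 3

    def test_novel_analog_kept(self, small_table, small_library):
        refs = sc.select_references(small_table, n=100)
        from qsarkit.diversity import maccs_fingerprints

        fps = maccs_fingerprints([r.smiles_canonical for r in refs],
                                 [r.compound_id for r in refs])
        near = small_library.near_duplicates[0]
        gated = sc.similarity_gate([(near, "near")], fps, 0.90)
        kept, removed = sc.exclude_known(gated, [r.smiles_canonical for r in refs])
        assert [g.name for g in kept] == ["near"]


class TestScreen:
    def test_near_duplicate_is_rank_one(self, trained_bundle, small_table, small_library):
        bundle, _ = trained_bundle
        refs = sc.select_references(small_table, n=100)
        hits = sc.screen(bundle, small_library.candidates, refs, threshold=0.90,
                         top_n=5, known_smiles=[r.smiles_canonical for r in small_table.records])
        assert hits["name"].iloc[0] == "near_dup_top"
        assert hits["rank"].iloc[0] == 1
        assert (hits["max_tanimoto"] >= 0.90).all()

    def test_references_as_candidates_all_excluded(self, trained_bundle, small_table):
        bundle, _ = trained_bundle
        refs = sc.select_references(small_table, n=10)
        cands = [(r.smiles_canonical, r.compound_id) for r in refs]
        hits = sc.screen(bundle, cands, refs, threshold=0.90, top_n=5)
        assert hits.empty
        assert "removed as known" in hits.attrs["status"]

    def test_top_n_larger_than_survivors(self, trained_bundle, small_table, small_library):
        bundle, _ = trained_bundle
        refs = sc.select_references(small_table, n=100)
        hits = sc.screen(bundle, small_library.candidates, refs, threshold=0.90,
                         top_n=500, known_smiles=[r.smiles_canonical for r in small_table.records])
        assert len(hits) >= 1  # all survivors returned, no padding

    def test_order_independence(self, trained_bundle, small_table, small_library):
        bundle, _ = trained_bundle
        refs = sc.select_references(small_table, n=100)
        known = [r.smiles_canonical for r in small_table.records]
        shuffled = list(small_library.candidates)
        np.random.RandomState(0).shuffle(shuffled)
        a = sc.screen(bundle, small_library.candidates, refs, 0.90, 5, known)
        b = sc.screen(bundle, shuffled, refs, 0.90, 5, known)
        assert a["smiles"].tolist() == b["smiles"].tolist()
        assert a["rank"].tolist() == b["rank"].tolist()

    def test_streaming_from_smi_file(self, tmp_path, trained_bundle, small_table, small_library):
        bundle, _ = trained_bundle
        small_library.write_smi(tmp_path / "lib.smi")
        refs = sc.select_references(small_table, n=100)
        hits = sc.screen(bundle, tmp_path / "lib.smi", refs, threshold=0.90,
                         top_n=5, known_smiles=[r.smiles_canonical for r in small_table.records])
        assert hits["name"].iloc[0] == "near_dup_top"
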