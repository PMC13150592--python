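"""Dictionary fingerprints, Morgan fingerprints, Tanimoto similarity,
and feature-table assembly."""
import numpy as np
import pandas as pd
import pytest
from rdkit import Chem
from rdkit.Chem import DataStructs, MACCSkeys

import bcrpqsar as bq
from bcrpqsar.fingerprints import (BitDef, bulk_max_tanimoto,
                                   load_spec_tsv, save_spec_tsv)
from bcrpqsar.records import ValidationError


@pytest.fixture(scope="module")
def specs():
    return bq.default_specs()


class TestDictionaryFingerprints:
    def test_absent_substructure_gives_zero(self):
        spec = bq.FingerprintSpec("t", [BitDef(0, "smarts", "c1ccccc1")])
        assert bq.compute_fingerprint("C", spec).bits[0] == 0

    def test_nitro_substituted_benzene_bit(self):
        spec = bq.funcgroups_spec()
        nitro_idx = next(b.index for b in spec.bits
                         if b.pattern == "O=[N+]([O-])c1ccccc1")
        on = bq.compute_fingerprint("O=[N+]([O-])c1ccccc1C", spec).bits
        off = bq.compute_fingerprint("CCO", spec).bits
        assert on[nitro_idx] == 1 and off[nitro_idx] == 0

    def test_maccs_dictionary_is_166_bits(self):
        assert len(bq.maccs166_spec()) == 166
        vec = bq.compute_fingerprint("CCO", bq.maccs166_spec())
        assert len(vec) == 166

    def test_maccs_agrees_with_reference_implementation(
            self, small_molecules):
        """Our table-driven MACCS matches RDKit's key generator
        (independent code path) bit for bit on generator molecules."""
        spec = bq.maccs166_spec()
        for smi in small_molecules[:25]:
            mine = bq.compute_fingerprint(smi, spec).bits
            ref = np.zeros(167, dtype=np.uint8)
            DataStructs.ConvertToNumpyArray(
                MACCSkeys.GenMACCSKeys(Chem.MolFromSmiles(smi)), ref)
            np.testing.assert_array_equal(mine, ref[1:])

    def test_min_count_semantics(self):
        spec = bq.FingerprintSpec("t", [
            BitDef(0, "smarts", "[OX2H]", 2, "two hydroxyls")])
        assert bq.compute_fingerprint("OCCO", spec).bits[0] == 1
        assert bq.compute_fingerprint("OCC", spec).bits[0] == 0

    def test_count_kinds(self):
        spec = bq.FingerprintSpec("t", [
            BitDef(0, "element_count", "N", 2),
            BitDef(1, "ring_count", "6:aromatic", 1),
            BitDef(2, "ring_count", "0:aromatic", 2)])
        bits = bq.compute_fingerprint("Nc1ccccc1N", spec).bits
        assert list(bits) == [1, 1, 0]
        bits = bq.compute_fingerprint("c1ccc(-c2ccccc2)cc1", spec).bits
        assert list(bits) == [0, 1, 1]

    def test_permutation_invariance(self):
        """Different atom orderings of one molecule give equal bits."""
        spec = bq.funcgroups_spec()
        a = bq.compute_fingerprint(
            bq.standardize_smiles("c1ccncc1CCO").smiles_std, spec).bits
        b = bq.compute_fingerprint(
            bq.standardize_smiles("OCCc1ccncc1").smiles_std, spec).bits
        np.testing.assert_array_equal(a, b)

    def test_every_shipped_bit_compiles_and_resolves(self, specs):
        for spec in specs:
            for b in spec.bits:
                smarts, _ = bq.bit_to_smarts(
                    [spec], f"{spec.name}:{b.index}")
                assert smarts
                if b.kind == "smarts":
                    assert Chem.MolFromSmarts(b.pattern) is not None

    def test_spec_tsv_round_trip(self, tmp_path):
        spec = bq.funcgroups_spec()
        path = tmp_path / "d.tsv"
        save_spec_tsv(spec, path)
        back = load_spec_tsv(path, name=spec.name)
        assert len(back) == len(spec)
        assert all(a.pattern == b.pattern and a.min_count == b.min_count
                   for a, b in zip(back.bits, spec.bits))

    def test_dense_index_invariant(self):
        with pytest.raises(ValidationError):
            bq.FingerprintSpec("t", [BitDef(1, "smarts", "C")])


class TestMorgan:
    def test_determinism(self):
        a = bq.morgan_fingerprint("CCO")
        b = bq.morgan_fingerprint("CCO")
        np.testing.assert_array_equal(a.bits, b.bits)

    def test_benzene_differs_from_pyridine_at_radius_2(self):
        a = bq.morgan_fingerprint("c1ccccc1", radius=2)
        b = bq.morgan_fingerprint("c1ccncc1", radius=2)
        assert (a.bits != b.bits).any()

    def test_radius_zero_only_atom_environments(self):
        # propane and butane share every size-1 atom environment
        a = bq.morgan_fingerprint("CCC", radius=0)
        b = bq.morgan_fingerprint("CCCC", radius=0)
        np.testing.assert_array_equal(a.bits, b.bits)

    def test_n_bits_must_be_power_of_two(self):
        with pytest.raises(ValidationError):
            bq.morgan_fingerprint("CCO", n_bits=1000)


def vec(bits, name="t"):
    return bq.BitVector(name, np.array(bits, dtype=np.uint8))


class TestTanimoto:
    def test_identity_and_disjoint(self):
        assert bq.tanimoto(vec([1, 1, 0]), vec([1, 1, 0])) == 1.0
        assert bq.tanimoto(vec([1, 0, 0]), vec([0, 1, 1])) == 0.0

    def test_hand_popcount(self):
        assert bq.tanimoto(vec([1, 1, 0, 0]), vec([1, 0, 1, 0])) == \
            pytest.approx(1 / 3)

    def test_symmetry_and_reference_agreement(self, small_molecules):
        """Matches RDKit's Tanimoto on real Morgan fingerprints."""
        fps = [bq.morgan_fingerprint(s) for s in small_molecules[:8]]
        rd = [Chem.RDKFingerprint(Chem.MolFromSmiles(s))
              for s in small_molecules[:8]]  # noqa: F841 (parse check)
        for i in range(4):
            for j in range(4, 8):
                mine = bq.tanimoto(fps[i], fps[j])
                assert mine == pytest.approx(bq.tanimoto(fps[j], fps[i]))
                bva = DataStructs.CreateFromBitString(
                    "".join(map(str, fps[i].bits)))
                bvb = DataStructs.CreateFromBitString(
                    "".join(map(str, fps[j].bits)))
                assert mine == pytest.approx(
                    DataStructs.TanimotoSimilarity(bva, bvb))

    def test_both_empty_is_zero_with_warning(self):
        with pytest.warns(UserWarning):
            assert bq.tanimoto(vec([0, 0]), vec([0, 0])) == 0.0

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValidationError):
            bq.tanimoto(vec([1, 0]), vec([1, 0, 1]))

    def test_one_minus_tanimoto_triangle_on_random_triples(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            a, b, c = (vec(rng.integers(0, 2, 24)) for _ in range(3))
            dab = 1 - bq.tanimoto(a, b)
            dbc = 1 - bq.tanimoto(b, c)
            dac = 1 - bq.tanimoto(a, c)
            assert dac <= dab + dbc + 1e-12


class TestMaxTanimoto:
    def test_query_in_reference_gives_one(self):
        q = vec([1, 0, 1])
        assert bq.max_tanimoto_to_set(q, [vec([0, 1, 0]), q]) == 1.0

    def test_singleton_reduction(self):
        q, r = vec([1, 1, 0]), vec([1, 0, 1])
        assert bq.max_tanimoto_to_set(q, [r]) == bq.tanimoto(q, r)

    def test_empty_reference_is_an_error(self):
        with pytest.raises(ValidationError):
            bq.max_tanimoto_to_set(vec([1]), [])

    def test_bulk_matches_brute_force_over_random_vectors(self):
        rng = np.random.default_rng(9)
        ref = [vec(rng.integers(0, 2, 32)) for _ in range(50)]
        queries = [vec(rng.integers(0, 2, 32)) for _ in range(10)]
        bulk = bulk_max_tanimoto(queries, ref)
        for q, b in zip(queries, bulk):
            brute = max(bq.tanimoto(q, r) for r in ref)
            assert b == pytest.approx(brute)


class TestFeatureTable:
    def test_single_spec_shape(self):
        t = bq.build_feature_table(["CCO", "CCN", "c1ccccc1"],
                                   [bq.maccs166_spec()])
        assert t.matrix.shape == (3, 166)
        assert set(np.unique(t.matrix)) <= {0.0, 1.0}

    def test_width_additivity_with_external_block(self):
        ext = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 5)),
                           columns=[f"d{i}" for i in range(5)])
        t = bq.build_feature_table(["CCO", "CCN", "CCC"],
                                   [bq.counts_spec(),
                                    bq.funcgroups_spec()], external=ext)
        assert t.p == len(bq.counts_spec()) + len(bq.funcgroups_spec()) + 5
        assert t.provenance[-1] == "external_descriptor"

    def test_misaligned_external_block_is_an_error(self):
        ext = pd.DataFrame(np.zeros((2, 1)), columns=["d"])
        with pytest.raises(ValidationError):
            bq.build_feature_table(["CCO", "CCN", "CCC"],
                                   [bq.counts_spec()], external=ext)

    def test_select_and_row_ops_preserve_alignment(self):
        t = bq.build_feature_table(["CCO", "CCN"], [bq.counts_spec()])
        sub = t.select(t.feature_names[:3])
        assert sub.p == 3 and sub.compound_ids == t.compound_ids
        rows = t.take_rows([1])
        assert rows.compound_ids == [t.compound_ids[1]]
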