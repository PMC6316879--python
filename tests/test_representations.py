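"""SMILES tokenization, enumeration, one-hot and image-embedding contracts."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from molhetero import representations as rep
from molhetero.errors import (
    CellCollisionError,
    EmptyCorpusError,
    InvalidSmilesError,
    LengthError,
    MissingPropertyError,
    UnknownTokenError,
)


class TestCanonicalize:
    def test_equivalent_serializations_agree(self):
        assert rep.canonicalize("OCC") == rep.canonicalize("CCO")

    def test_idempotent(self):
        c = rep.canonicalize("CCO")
        assert rep.canonicalize(c) == c

    @pytest.mark.parametrize("bad", ["C(", "", "notasmiles", "C1CC"])
    def test_unparseable_raises(self, bad):
        with pytest.raises(InvalidSmilesError):
            rep.canonicalize(bad)


class TestEnumerateSmiles:
    def test_all_variants_same_molecule(self, fixture_molecules):
        for smi in fixture_molecules:
            for e in rep.enumerate_smiles(smi, 5, seed=7):
                assert rep.canonicalize(e) == rep.canonicalize(smi)

    def test_toluene_yields_ten_valid_forms(self):
        out = rep.enumerate_smiles("Cc1ccccc1", 10, seed=3)
        assert len(out) == 10
        toluene = rep.canonicalize("Cc1ccccc1")
        assert all(rep.canonicalize(s) == toluene for s in out)

    def test_single_atom_has_one_form(self):
        assert rep.enumerate_smiles("C", 5, seed=0) == ["C"] * 5

    def test_ethanol_within_brute_force_set(self):
        # all 3! atom orders of ethanol, serialized non-canonically
        mol = Chem.MolFromSmiles("CCO")
        brute = {
            Chem.MolToSmiles(Chem.RenumberAtoms(mol, list(perm)),
                             canonical=False)
            for perm in itertools.permutations(range(3))
        }
        got = set(rep.enumerate_smiles("CCO", 50, seed=11))
        assert got <= brute

    def test_deterministic_for_seed(self):
        a = rep.enumerate_smiles("CC(=O)N", 20, seed=5)
        b = rep.enumerate_smiles("CC(=O)N", 20, seed=5)
        assert a == b


class TestAlphabet:
    def test_character_census(self):
        alpha = rep.build_alphabet(["CCO"])
        assert set(alpha.tokens) == {rep.PAD, rep.START, rep.END, "C", "O"}
        assert len(alpha) == 5

    def test_chlorine_is_single_token(self):
        alpha = rep.build_alphabet(["CCl"])
        assert "Cl" in alpha.tokens
        assert "l" not in alpha.tokens
        assert rep.tokenize("CCl") == ["C", "Cl"]

    def test_digits_only_with_rings(self):
        no_rings = rep.build_alphabet(["CCO", "C=O"])
        with_rings = rep.build_alphabet(["C1CC1"])
        assert not any(t.isdigit() for t in no_rings.tokens)
        assert "1" in with_rings.tokens

    def test_empty_corpus_raises(self):
        with pytest.raises(EmptyCorpusError):
            rep.build_alphabet([])

    def test_stable_order_and_json_roundtrip(self, tmp_path):
        alpha1 = rep.build_alphabet(["CCO", "CNC"])
        alpha2 = rep.build_alphabet(["CCO", "CNC"])
        assert alpha1.tokens == alpha2.tokens
        alpha1.to_json(tmp_path / "alpha.json")
        loaded = rep.TokenAlphabet.from_json(tmp_path / "alpha.json")
        assert loaded == alpha1


class TestVectorize:
    def test_hand_written_layout(self):
        alpha = rep.TokenAlphabet(tokens=(rep.PAD, rep.START, rep.END, "C"))
        mat = rep.vectorize("C", alpha, maxlen=4)
        expected = np.zeros((4, 4))
        expected[0, 1] = 1  # start
        expected[1, 3] = 1  # C
        expected[2, 2] = 1  # end
        expected[3, 0] = 1  # pad
        np.testing.assert_array_equal(mat, expected)

    def test_round_trip_whole_corpus(self, fixture_molecules, alphabet, maxlen):
        for smi in fixture_molecules:
            mat = rep.vectorize(smi, alphabet, maxlen)
            assert rep.devectorize(mat, alphabet) == smi
            np.testing.assert_array_equal(mat.sum(axis=1), np.ones(maxlen))

    def test_unknown_token_raises(self):
        alpha = rep.build_alphabet(["CCO"])
        with pytest.raises(UnknownTokenError):
            rep.vectorize("CN", alpha, maxlen=10)

    def test_too_long_raises(self, alphabet):
        with pytest.raises(LengthError):
            rep.vectorize("CCO", alphabet, maxlen=4)


class TestAtomChannelTable:
    ELEMENTS = ["C", "N", "O", "F", "S", "Cl"]

    def test_values_in_unit_interval_with_extremes(self):
        table = rep.atom_channel_table(self.ELEMENTS)
        arr = np.array([table.channels(el) for el in self.ELEMENTS])
        assert arr.min() >= 0.0 and arr.max() <= 1.0
        for ch in range(3):
            assert arr[:, ch].min() == pytest.approx(0.0)
            assert arr[:, ch].max() == pytest.approx(1.0)

    def test_matches_independent_pca_pipeline(self):
        # oracle: sklearn PCA on the standardized property matrix; min-max
        # scaled scores must agree per channel up to the overall sign flip
        from sklearn.decomposition import PCA
        from molhetero.atomdata import DEFAULT_PROPERTIES, atomic_properties

        rows = np.array([[atomic_properties(el)[p] for p in DEFAULT_PROPERTIES]
                         for el in self.ELEMENTS])
        z = (rows - rows.mean(0)) / rows.std(0)
        scores = PCA(n_components=3).fit_transform(z)
        lo, hi = scores.min(0), scores.max(0)
        oracle = (scores - lo) / (hi - lo)

        table = rep.atom_channel_table(self.ELEMENTS)
        ours = np.array([table.channels(el) for el in self.ELEMENTS])
        for ch in range(3):
            direct = np.allclose(ours[:, ch], oracle[:, ch], atol=1e-8)
            flipped = np.allclose(ours[:, ch], 1.0 - oracle[:, ch], atol=1e-8)
            assert direct or flipped

    def test_too_few_elements_raises(self):
        with pytest.raises(ValueError):
            rep.atom_channel_table(["C", "N", "O"])

    def test_unknown_element_raises(self):
        with pytest.raises(MissingPropertyError):
            rep.atom_channel_table(["C", "N", "O", "Xx"])


@pytest.fixture(scope="module")
def table():
    return rep.atom_channel_table(["C", "N", "O", "F", "S", "Cl"])


class TestEmbedImage:

    def test_benzene_has_six_aromatic_atom_cells(self, table):
        img = rep.embed_image("c1ccccc1", table, rotation=0.0)
        assert img.shape == (80, 80, 5)
        assert int((img[:, :, 4] == 1.0).sum()) == 6
        assert set(np.unique(img[:, :, 4])) <= {0.0, 1.0}

    def test_empty_regions_zero_and_atom_channels(self, table):
        img = rep.embed_image("CCO", table, rotation=0.0)
        occupied = img[:, :, 0:3].sum(axis=2) > 0
        assert occupied.sum() >= 2  # carbon may sit at channel value 0
        assert img[~occupied][:, 0:3].sum() == 0.0

    def test_random_rotation_deterministic_per_seed(self, table):
        a = rep.embed_image("CC=O", table, rotation="random", seed=9)
        b = rep.embed_image("CC=O", table, rotation="random", seed=9)
        np.testing.assert_array_equal(a, b)

    def test_full_turn_invariance(self, table):
        a = rep.embed_image("CCN", table, rotation=25.0)
        b = rep.embed_image("CCN", table, rotation=385.0)
        np.testing.assert_allclose(a, b)

    def test_grid_overflow_raises(self, table):
        from molhetero.errors import GridOverflowError

        with pytest.raises(GridOverflowError):
            rep.embed_image("CCCCCCCCCC", table, height=6, width=6,
                            rotation=0.0)

    def test_collision_raises_at_coarse_resolution(self, table):
        with pytest.raises(CellCollisionError):
            rep.embed_image("C1CC1", table, resolution=100.0, rotation=0.0)
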