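"""Similarity metrics, correlations, enumeration challenge, nearest neighbors."""

import itertools

import numpy as np
import pytest
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from molhetero import latent
from molhetero.errors import DegenerateDataError, DimensionError
from molhetero.latent import (
    AlignmentParams,
    alignment_score,
    fingerprint_similarity,
    latent_similarity,
)


from oracles import exhaustive_alignment_score


class TestLatentSimilarity:
    def test_unit_distance_is_zero(self):
        assert latent_similarity(np.zeros(4), np.array([1, 0, 0, 0.0])) == 0.0

    def test_distance_ten(self):
        v = np.zeros(3)
        w = np.array([10.0, 0, 0])
        assert latent_similarity(v, w) == pytest.approx(-np.log(10.0))

    def test_identical_vectors_floored(self):
        v = np.ones(5)
        assert latent_similarity(v, v) == pytest.approx(-np.log(1e-12))

    def test_symmetric_and_translation_invariant(self, rng):
        a, b = rng.normal(size=(2, 8))
        shift = rng.normal(size=8)
        assert latent_similarity(a, b) == pytest.approx(latent_similarity(b, a))
        assert latent_similarity(a + shift, b + shift) == pytest.approx(
            latent_similarity(a, b))

    def test_dimension_mismatch(self):
        with pytest.raises(DimensionError):
            latent_similarity(np.zeros(3), np.zeros(4))


class TestFingerprintSimilarity:
    def test_same_molecule_different_smiles(self):
        assert fingerprint_similarity("CCO", "OCC") == 1.0

    def test_matches_raw_bitset_tanimoto(self):
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)
        a = gen.GetFingerprint(Chem.MolFromSmiles("C"))
        b = gen.GetFingerprint(Chem.MolFromSmiles("CCCCCCCC"))
        bits_a = set(a.GetOnBits())
        bits_b = set(b.GetOnBits())
        expected = len(bits_a & bits_b) / len(bits_a | bits_b)
        got = fingerprint_similarity("C", "CCCCCCCC")
        assert got == pytest.approx(expected)
        assert got < 1.0

    def test_symmetric(self):
        assert fingerprint_similarity("CCO", "C1CC1") == pytest.approx(
            fingerprint_similarity("C1CC1", "CCO"))

    def test_identity_on_fixture(self, fixture_molecules):
        for smi in fixture_molecules[:25]:
            assert fingerprint_similarity(smi, smi) == 1.0


class TestAlignmentScore:
    def test_two_matches(self):
        assert alignment_score("CC", "CC") == 2.0

    def test_gap_case(self):
        assert alignment_score("CCO", "CO") == pytest.approx(1.5)

    def test_mismatch_case(self):
        assert alignment_score("CC", "CO") == pytest.approx(0.0)

    def test_agrees_with_exhaustive_oracle(self):
        alphabet = "CNO()1"
        rng = np.random.default_rng(0)
        pairs = []
        for _ in range(60):
            n1, n2 = rng.integers(1, 6, size=2)
            s1 = "".join(rng.choice(list(alphabet), n1))
            s2 = "".join(rng.choice(list(alphabet), n2))
            pairs.append((s1, s2))
        for s1, s2 in pairs:
            assert alignment_score(s1, s2) == pytest.approx(
                exhaustive_alignment_score(s1, s2)), (s1, s2)

    def test_symmetric(self):
        assert alignment_score("CCO", "OC1") == pytest.approx(
            alignment_score("OC1", "CCO"))

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            alignment_score("", "CC")

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            AlignmentParams(gap_open=-0.05, gap_extend=-0.5)


class TestWithTrainedEncoder:
    def test_same_molecule_same_vector(self, split_parts):
        encoder, _, _ = split_parts
        from molhetero.model import encode

        vecs = encode(encoder, ["CCO", "CCO"], representation="canonical")
        np.testing.assert_array_equal(vecs[0], vecs[1])
        assert (vecs >= 0).all()

    def test_empty_list(self, split_parts):
        encoder, _, _ = split_parts
        from molhetero.model import encode

        assert encode(encoder, [], representation="canonical").shape[0] == 0

    def test_correlations_in_unit_interval(self, split_parts,
                                           tiny_trained_model):
        encoder, _, _ = split_parts
        _, _, train_set, test_set = tiny_trained_model
        r2_fp, r2_seq = latent.similarity_correlations(test_set[0], train_set,
                                                       encoder)
        assert 0.0 <= r2_fp <= 1.0
        assert 0.0 <= r2_seq <= 1.0

    def test_self_correlation_is_one(self, split_parts, tiny_trained_model):
        """Feeding the fingerprint metric as both variables gives R^2 = 1."""
        from scipy import stats

        encoder, _, _ = split_parts
        _, _, train_set, test_set = tiny_trained_model
        triples = latent.similarity_triples(test_set[0], train_set, encoder)
        fp = np.array([t.fp_sim for t in triples])
        assert stats.pearsonr(fp, fp).statistic ** 2 == pytest.approx(1.0)

    def test_degenerate_testset_raises(self, split_parts):
        encoder, _, _ = split_parts
        with pytest.raises(DegenerateDataError):
            latent.similarity_correlations("CCO", ["CCN", "CCN"], encoder)

    def test_challenge_contract(self, split_parts, tiny_trained_model):
        encoder, _, _ = split_parts
        _, _, train_set, test_set = tiny_trained_model
        mols = [m for m in test_set if len(m) > 2][:2] or test_set[:2]
        result = latent.enumeration_challenge(encoder, mols, n_enum=5,
                                              background=train_set, seed=0)
        for can, proj in result.projections.items():
            assert proj.shape == (5, 2)
            assert result.spreads[can] >= 0.0
        assert result.background_projection.shape == (len(train_set), 2)

    def test_challenge_identical_strings_zero_spread(self, split_parts):
        encoder, _, _ = split_parts
        # methane has a single serialization, so all enumerations coincide
        result = latent.enumeration_challenge(encoder, ["C"], n_enum=4,
                                              background=["CC", "CCO", "CN"],
                                              seed=0)
        assert result.spreads["C"] == 0.0

    def test_challenge_validation(self, split_parts):
        encoder, _, _ = split_parts
        with pytest.raises(ValueError):
            latent.enumeration_challenge(encoder, ["CC"], n_enum=5,
                                         background=["C"], seed=0)
        with pytest.raises(ValueError):
            latent.enumeration_challenge(encoder, ["CC"], n_enum=1,
                                         background=["C", "N"], seed=0)


class TestNearestNeighbors:
    def test_query_in_library_ranks_first(self, split_parts):
        encoder, _, _ = split_parts
        library = ["CCO", "CC", "CNC", "C=O"]
        out = latent.nearest_neighbors("CC", encoder, library, k=4)
        assert out[0] == "CC"

    def test_full_k_is_permutation(self, split_parts):
        encoder, _, _ = split_parts
        library = ["CCO", "CC", "CNC", "C=O", "C#N"]
        out = latent.nearest_neighbors("CO", encoder, library, k=5)
        assert sorted(out) == sorted(library)

    def test_matches_brute_force_sort(self, split_parts, rng):
        """Ranking agrees with an independent distance sort on raw vectors."""
        encoder, _, _ = split_parts
        from molhetero.model import encode

        library = ["C", "N", "O", "CC", "CO", "CN", "C=O", "CCO", "CCN",
                    "OCO", "C#C", "C#N", "CNC", "COC", "C=C", "CC=O",
                    "NCO", "OO", "NN", "CCC"]
        query = "CC#N"
        vecs = encode(encoder, [query] + library, representation="canonical")
        dists = np.linalg.norm(vecs[1:] - vecs[0], axis=1)
        oracle = [library[i] for i in
                  sorted(range(len(library)), key=lambda i: (dists[i], i))]
        got = latent.nearest_neighbors(query, encoder, library,
                                       k=len(library))
        assert got == oracle

    def test_validation(self, split_parts):
        encoder, _, _ = split_parts
        with pytest.raises(ValueError):
            latent.nearest_neighbors("C", encoder, [], k=1)
        with pytest.raises(ValueError):
            latent.nearest_neighbors("C", encoder, ["CC"], k=5)
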