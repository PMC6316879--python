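"""Fixture enumeration, splits, standardization, pairs and synthetic labels."""

import itertools

import numpy as np
import pytest
from rdkit import Chem

from molhetero import datasets
from molhetero.datasets import (
    FixtureSpec,
    PairingMode,
    generate_fixture_molecules,
    make_training_pairs,
    split_train_test,
    standardize_chembl_like,
    structure_score,
    synthetic_property,
)
from molhetero.errors import EmptyFixtureError
from molhetero.representations import canonicalize


def brute_force_molecules(max_atoms, elements):
    """Independent oracle: enumerate all labelled multigraphs directly.

    For every atom count, element assignment and symmetric bond-order
    matrix (orders 0-3), keep molecules that RDKit sanitizes without
    valence errors or added charges, are connected, and respect the
    element valence caps; deduplicate by canonical SMILES. Exponential, so
    only usable for max_atoms <= 3.
    """
    caps = {"C": 4, "N": 3, "O": 2, "F": 1}
    bond_types = {1: Chem.BondType.SINGLE, 2: Chem.BondType.DOUBLE,
                  3: Chem.BondType.TRIPLE}
    found = set()
    for n in range(1, max_atoms + 1):
        pairs = list(itertools.combinations(range(n), 2))
        for elems in itertools.product(elements, repeat=n):
            for orders in itertools.product(range(4), repeat=len(pairs)):
                # valence pre-filter
                degree = [0] * n
                for (i, j), o in zip(pairs, orders):
                    degree[i] += o
                    degree[j] += o
                if any(degree[i] > caps[elems[i]] for i in range(n)):
                    continue
                if n > 1 and any(d == 0 for d in degree):
                    continue  # disconnected atom
                rw = Chem.RWMol()
                for el in elems:
                    rw.AddAtom(Chem.Atom(el))
                for (i, j), o in zip(pairs, orders):
                    if o:
                        rw.AddBond(i, j, bond_types[o])
                mol = rw.GetMol()
                try:
                    Chem.SanitizeMol(mol)
                except Exception:
                    continue
                if len(Chem.GetMolFrags(mol)) != 1:
                    continue
                found.add(Chem.MolToSmiles(mol))
    return found


class TestFixtureGeneration:
    def test_single_atoms(self):
        spec = FixtureSpec(max_heavy_atoms=1, elements=("C", "N", "O"))
        assert set(generate_fixture_molecules(spec)) == {"C", "N", "O"}

    def test_two_atoms_no_rings_exact_set(self):
        # all element pairs x bond orders filtered by valence (C<=4, O<=2):
        # molecular oxygen O=O is valence-valid and therefore included
        spec = FixtureSpec(max_heavy_atoms=2, elements=("C", "O"),
                           allow_rings=False)
        got = set(generate_fixture_molecules(spec))
        expected = {canonicalize(s)
                    for s in ["C", "O", "CC", "CO", "OO", "C=C", "C=O",
                              "C#C", "O=O"]}
        assert got == expected

    @pytest.mark.parametrize("max_atoms", [2, 3])
    def test_matches_brute_force_oracle(self, max_atoms):
        spec = FixtureSpec(max_heavy_atoms=max_atoms, elements=("C", "N", "O"))
        got = set(generate_fixture_molecules(spec))
        assert got == brute_force_molecules(max_atoms, ("C", "N", "O"))

    def test_no_duplicates_under_canonicalization(self, fixture_molecules):
        canon = [canonicalize(s) for s in fixture_molecules]
        assert len(canon) == len(set(canon))

    def test_n_max_subsample_deterministic(self):
        spec = FixtureSpec(max_heavy_atoms=3, n_max=20, seed=5)
        a = generate_fixture_molecules(spec)
        b = generate_fixture_molecules(spec)
        assert a == b and len(a) == 20

    def test_invalid_spec_raises(self):
        with pytest.raises(ValueError):
            FixtureSpec(max_heavy_atoms=0)
        with pytest.raises(ValueError):
            FixtureSpec(elements=())
        with pytest.raises(ValueError):
            FixtureSpec(elements=("C", "Si"))


class TestSplit:
    def test_ratio_90_10(self):
        mols = [f"{'C' * (i + 1)}" for i in range(10)]
        train, test = split_train_test(mols, 0.9, seed=0)
        assert len(train) == 9 and len(test) == 1

    def test_disjoint_union_and_determinism(self, fixture_molecules):
        t1, s1 = split_train_test(fixture_molecules, 0.5, seed=3)
        t2, s2 = split_train_test(fixture_molecules, 0.5, seed=3)
        assert (t1, s1) == (t2, s2)
        assert not set(t1) & set(s1)
        assert set(t1) | set(s1) == set(fixture_molecules)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            split_train_test(["C"], 0.9)
        with pytest.raises(ValueError):
            split_train_test(["C", "N"], 1.5)


class TestStandardizer:
    def test_salt_strip_and_neutralize(self):
        res = standardize_chembl_like("CC(=O)[O-].[Na+]")
        assert res.accepted and res.smiles == canonicalize("CC(=O)O")

    def test_stereo_removed(self):
        res = standardize_chembl_like("C[C@H](N)C(=O)O")
        assert res.accepted and res.smiles == canonicalize("CC(N)C(=O)O")

    def test_too_long_rejected(self):
        res = standardize_chembl_like("C" * 101)
        assert not res.accepted and res.reason == "too_long"

    def test_unparseable_rejected(self):
        res = standardize_chembl_like("C((")
        assert not res.accepted and res.reason == "unparseable"

    def test_permanent_charge_rejected(self):
        res = standardize_chembl_like("C[N+](C)(C)C")
        assert not res.accepted and res.reason == "permanent_charge"

    def test_output_never_has_forbidden_tokens(self, fixture_molecules):
        probes = ["CC(=O)[O-].[Na+]", "C[C@H](N)C(=O)O", "c1ccccc1[O-]",
                  "CC.[Cl-].[NH4+]"] + fixture_molecules[:20]
        for smi in probes:
            res = standardize_chembl_like(smi)
            if res.accepted:
                assert "." not in res.smiles
                assert "@" not in res.smiles
                assert "+" not in res.smiles and "-" not in res.smiles


class TestTrainingPairs:
    def test_can2can_identity(self):
        mols = ["CCO", "CC", "C"]
        pairs = make_training_pairs(mols, PairingMode("can2can"), seed=0)
        assert sorted(pairs) == sorted((canonicalize(m), canonicalize(m))
                                       for m in mols)

    def test_single_atom_degenerate_enumeration(self):
        pairs = make_training_pairs(["C"], PairingMode("enum2can", n_enum=50),
                                    seed=0)
        assert pairs == [("C", "C")] * 50

    @pytest.mark.parametrize("mode", ["can2enum", "enum2can", "enum2enum"])
    def test_pair_counts_and_same_molecule(self, mode):
        mols = ["CCO", "CC=O", "CNC"]
        pairs = make_training_pairs(mols, PairingMode(mode, n_enum=10), seed=1)
        assert len(pairs) == 30
        for inp, tgt in pairs:
            assert canonicalize(inp) == canonicalize(tgt)

    def test_can2enum_inputs_are_canonical(self):
        mols = [canonicalize(s) for s in ["CCO", "CC=O", "CNC"]]
        pairs = make_training_pairs(mols, PairingMode("can2enum", n_enum=50),
                                    seed=2)
        assert len(pairs) == 150
        assert {inp for inp, _ in pairs} <= set(mols)

    def test_enum2enum_prefers_distinct_strings(self):
        pairs = make_training_pairs(["CC(=O)NC"],
                                    PairingMode("enum2enum", n_enum=20),
                                    seed=3)
        distinct = sum(1 for a, b in pairs if a != b)
        assert distinct >= 15  # the molecule admits many serializations

    def test_deterministic(self):
        mols = ["CCO", "CNC"]
        a = make_training_pairs(mols, PairingMode("can2enum", n_enum=5), seed=9)
        b = make_training_pairs(mols, PairingMode("can2enum", n_enum=5), seed=9)
        assert a == b


class TestSyntheticProperty:
    def test_zero_noise_equals_structure_function(self):
        mols = ["CCO", "c1ccccc1", "C#N"]
        labels = synthetic_property(mols, noise_sd=0.0, seed=0)
        np.testing.assert_allclose(labels,
                                   [structure_score(m) for m in mols])

    def test_heteroatom_weight_difference(self):
        diff = structure_score("CCO") - structure_score("CCC")
        assert diff == pytest.approx(datasets.PROPERTY_WEIGHTS["heteroatoms"])

    def test_seeded_noise_deterministic(self):
        mols = ["CCO", "CCC", "CCN"]
        a = synthetic_property(mols, noise_sd=0.5, seed=4)
        b = synthetic_property(mols, noise_sd=0.5, seed=4)
        np.testing.assert_array_equal(a, b)
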