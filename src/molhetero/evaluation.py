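"""Reconstruction-error taxonomy, sampling statistics, dead-neuron scan.

Decoding errors are classified hierarchically: an output string either is
not a valid SMILES, or decodes to the wrong molecule, in which case the
disagreement is localized to the generalized scaffold, the molecular sum
formula and/or the bond-type census. Outputs that get all three right but
are still a different molecule assembled the right parts in a wrong order.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

from .errors import InvalidSmilesError
from .representations import mol_from_smiles, try_canonicalize
from .latent import fingerprint_similarity
from .model import Encoder, encode


@dataclass(frozen=True)
class ReconstructionReport:
    """Per-molecule decoding flags; molecule-level flags are None when the
    decoded string is not a valid SMILES."""

    valid: bool
    same_molecule: bool | None = None
    same_scaffold: bool | None = None
    same_formula: bool | None = None
    same_bonds: bool | None = None


@dataclass(frozen=True)
class SamplingStats:
    n: int
    unique_smiles: int
    pct_correct_mol: float
    unique_smiles_correct: int
    unique_molecules: int
    avg_fp_similarity: float
    avg_fp_defined: bool = True


def generalized_scaffold(smiles: str) -> str:
    """Generic Bemis-Murcko-style skeleton with side chains retained.

    Every atom is made carbon-like and every bond single on the whole
    molecule (side-chain atoms included), so two molecules share a
    scaffold exactly when their heavy-atom graphs are isomorphic. Isolated
    behind one function so the generalization recipe can be swapped.
    """
    mol = mol_from_smiles(smiles)
    generic = MurckoScaffold.MakeScaffoldGeneric(mol)
    return Chem.MolToSmiles(generic)


def sum_formula(smiles: str) -> str:
    """Hill-order molecular formula including implicit hydrogens."""
    return rdMolDescriptors.CalcMolFormula(mol_from_smiles(smiles))


def bond_census(smiles: str) -> dict[str, int]:
    """Counts of single, double, triple and aromatic bonds (aromatic bonds
    are their own class, not resolved to alternating single/double)."""
    mol = mol_from_smiles(smiles)
    census = {"single": 0, "double": 0, "triple": 0, "aromatic": 0}
    for bond in mol.GetBonds():
        bt = bond.GetBondType()
        if bt == Chem.BondType.AROMATIC:
            census["aromatic"] += 1
        elif bt == Chem.BondType.SINGLE:
            census["single"] += 1
        elif bt == Chem.BondType.DOUBLE:
            census["double"] += 1
        elif bt == Chem.BondType.TRIPLE:
            census["triple"] += 1
    return census


def reconstruction_report(input_smiles: str, decoded: str) -> ReconstructionReport:
    """Classify one decoded string against its input molecule."""
    input_can = try_canonicalize(input_smiles)
    if input_can is None:
        raise InvalidSmilesError(f"unparseable input SMILES: {input_smiles!r}")
    decoded_can = try_canonicalize(decoded)
    if decoded_can is None:
        return ReconstructionReport(valid=False)
    same_mol = decoded_can == input_can
    if same_mol:
        return ReconstructionReport(valid=True, same_molecule=True,
                                    same_scaffold=True, same_formula=True,
                                    same_bonds=True)
    return ReconstructionReport(
        valid=True,
        same_molecule=False,
        same_scaffold=(generalized_scaffold(decoded_can)
                       == generalized_scaffold(input_can)),
        same_formula=sum_formula(decoded_can) == sum_formula(input_can),
        same_bonds=bond_census(decoded_can) == bond_census(input_can),
    )


def aggregate_errors(reports: list[ReconstructionReport]) -> dict:
    """Partition the valid-but-wrong molecules into Venn regions.

    Region keys name which of {scaffold, formula, bonds} are wrong;
    ``wrong_order`` collects molecules with all three right but still a
    different molecule. Marginal counts (any wrong scaffold/formula/bonds)
    are reported alongside.
    """
    if not reports:
        raise ValueError("no reports to aggregate")
    n = len(reports)
    invalid = sum(1 for r in reports if not r.valid)
    correct = sum(1 for r in reports if r.valid and r.same_molecule)
    wrong = [r for r in reports if r.valid and not r.same_molecule]
    regions = {
        "scaffold_only": 0, "formula_only": 0, "bonds_only": 0,
        "scaffold_formula": 0, "scaffold_bonds": 0, "formula_bonds": 0,
        "scaffold_formula_bonds": 0, "wrong_order": 0,
    }
    for r in wrong:
        key = []
        if not r.same_scaffold:
            key.append("scaffold")
        if not r.same_formula:
            key.append("formula")
        if not r.same_bonds:
            key.append("bonds")
        if not key:
            regions["wrong_order"] += 1
        elif len(key) == 1:
            regions[key[0] + "_only"] += 1
        else:
            regions["_".join(key)] += 1
    marginals = {
        "wrong_scaffold": sum(1 for r in wrong if not r.same_scaffold),
        "wrong_formula": sum(1 for r in wrong if not r.same_formula),
        "wrong_bonds": sum(1 for r in wrong if not r.same_bonds),
    }
    return {
        "n": n,
        "invalid": invalid,
        "correct_molecule": correct,
        "valid_but_wrong": len(wrong),
        "venn": regions,
        "marginals": marginals,
    }


def sampling_statistics(samples: list[str], reference: str) -> SamplingStats:
    """De-novo sampling statistics against a reference molecule.

    Invalid samples count toward ``n`` but are excluded from the
    molecule-level tallies and the average fingerprint similarity (which
    includes correct-molecule samples).
    """
    if not samples:
        raise ValueError("samples must be non-empty")
    ref_can = try_canonicalize(reference)
    if ref_can is None:
        raise InvalidSmilesError(f"unparseable reference: {reference!r}")
    n = len(samples)
    unique_smiles = len(set(samples))
    valid_mols = [(s, try_canonicalize(s)) for s in samples]
    valid = [(s, c) for s, c in valid_mols if c is not None]
    correct = [(s, c) for s, c in valid if c == ref_can]
    fp_sims = [fingerprint_similarity(ref_can, c) for _, c in valid]
    return SamplingStats(
        n=n,
        unique_smiles=unique_smiles,
        pct_correct_mol=100.0 * len(correct) / n,
        unique_smiles_correct=len({s for s, _ in correct}),
        unique_molecules=len({c for _, c in valid}),
        # sorted before averaging so the statistic is exactly invariant to
        # sample order (float addition is not associative)
        avg_fp_similarity=float(np.mean(np.sort(fp_sims))) if fp_sims else 0.0,
        avg_fp_defined=bool(fp_sims),
    )


def dead_neuron_fraction(encoder: Encoder, molecules: list[str]) -> float:
    """Fraction of code dimensions that stay at exactly 0 for every input.

    With a ReLU code layer a dimension is dead when its pre-activation is
    never positive over the probe set.
    """
    if not molecules:
        raise ValueError("molecules must be non-empty")
    codes = encode(encoder, molecules, representation="canonical")
    active = (codes > 0.0).any(axis=0)
    return float(1.0 - active.mean())


def write_error_report_json(path: str | Path, partition: dict) -> None:
    Path(path).write_text(json.dumps(partition, indent=1))


def write_reports_csv(path: str | Path, molecules: list[str],
                      decoded: list[str],
                      reports: list[ReconstructionReport]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["input_smiles", "decoded", "valid", "same_molecule",
                         "same_scaffold", "same_formula", "same_bonds"])
        for smi, dec, r in zip(molecules, decoded, reports):
            row = [smi, dec] + [
                "" if v is None else int(v)
                for v in (r.valid, r.same_molecule, r.same_scaffold,
                          r.same_formula, r.same_bonds)
            ]
            writer.writerow(row)
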