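"""Synthetic fixture molecules, splits, standardization and training pairs.

The fixture generator exhaustively enumerates all valence-valid connected
molecules up to a heavy-atom budget over a small element set. It emulates
the fully-enumerated character of the GDB databases at desk scale, so a
train/test split still contains near-neighbours of every molecule — the
regime in which sequence autoencoders can be driven to near-perfect
reconstruction.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors, rdMolDescriptors

from .errors import EmptyFixtureError
from .representations import canonicalize, enumerate_smiles, mol_from_smiles

VALENCE_CAPS = {"C": 4, "N": 3, "O": 2, "F": 1}

_BOND_TYPES = {
    1: Chem.BondType.SINGLE,
    2: Chem.BondType.DOUBLE,
    3: Chem.BondType.TRIPLE,
}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the exhaustive fixture set."""

    max_heavy_atoms: int = 5
    elements: tuple[str, ...] = ("C", "N", "O")
    allow_rings: bool = True
    n_max: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.max_heavy_atoms < 1:
            raise ValueError("max_heavy_atoms must be >= 1")
        if not self.elements:
            raise ValueError("elements must be non-empty")
        for el in self.elements:
            if el not in VALENCE_CAPS:
                raise ValueError(f"unsupported element {el!r}")


@dataclass(frozen=True)
class PairingMode:
    """Encoder/decoder data pairing, named encoder2decoder."""

    mode: str = "can2can"
    n_enum: int = 10

    _MODES = ("can2can", "can2enum", "enum2can", "enum2enum", "img2can")

    def __post_init__(self):
        if self.mode not in self._MODES:
            raise ValueError(f"mode must be one of {self._MODES}")
        if self.n_enum < 1:
            raise ValueError("n_enum must be >= 1")


def _free_valence(mol: Chem.Mol) -> list[int]:
    return [a.GetTotalNumHs() for a in mol.GetAtoms()]


def _canon(mol: Chem.Mol) -> str | None:
    try:
        Chem.SanitizeMol(mol)
        return Chem.MolToSmiles(mol)
    except Exception:
        return None


def _grow_by_one_atom(smis: set[str], elements: tuple[str, ...]) -> set[str]:
    """All molecules obtained by bonding one new atom to any free valence."""
    out: set[str] = set()
    for smi in smis:
        base = Chem.MolFromSmiles(smi)
        fv = _free_valence(base)
        for i, free in enumerate(fv):
            if free == 0:
                continue
            for el in elements:
                for order in range(1, min(free, VALENCE_CAPS[el], 3) + 1):
                    rw = Chem.RWMol(base)
                    j = rw.AddAtom(Chem.Atom(el))
                    rw.AddBond(i, j, _BOND_TYPES[order])
                    c = _canon(rw)
                    if c:
                        out.add(c)
    return out


def _close_under_bond_increments(smis: set[str], allow_rings: bool) -> set[str]:
    """Close a set under single-step bond additions/order raises.

    A step either adds a single bond between two non-bonded atoms with free
    valence (creating a ring) or raises an existing bond's order by one.
    With ``allow_rings=False`` only order raises are applied.
    """
    seen = set(smis)
    queue = list(smis)
    while queue:
        base = Chem.MolFromSmiles(queue.pop())
        Chem.Kekulize(base, clearAromaticFlags=True)
        fv = _free_valence(base)
        n = base.GetNumAtoms()
        for i in range(n):
            if fv[i] == 0:
                continue
            for j in range(i + 1, n):
                if fv[j] == 0:
                    continue
                bond = base.GetBondBetweenAtoms(i, j)
                if bond is None and not allow_rings:
                    continue
                rw = Chem.RWMol(base)
                if bond is None:
                    rw.AddBond(i, j, Chem.BondType.SINGLE)
                else:
                    order = int(bond.GetBondTypeAsDouble())
                    if order >= 3:
                        continue
                    rw.GetBondBetweenAtoms(i, j).SetBondType(
                        _BOND_TYPES[order + 1]
                    )
                c = _canon(rw)
                if c and c not in seen:
                    seen.add(c)
                    queue.append(c)
    return seen


def generate_fixture_molecules(spec: FixtureSpec) -> list[str]:
    """Exhaustively enumerate canonical SMILES up to the heavy-atom budget.

    Generation grows molecules atom by atom and closes each size class
    under bond additions/order raises, deduplicating by canonical SMILES;
    this reaches every valence-valid connected molecule. If ``n_max`` caps
    the result, a seeded subsample of the sorted set is returned.
    """
    single = {canonicalize(el) for el in spec.elements}
    sizes: dict[int, set[str]] = {1: single}
    for size in range(2, spec.max_heavy_atoms + 1):
        grown = _grow_by_one_atom(sizes[size - 1], spec.elements)
        sizes[size] = _close_under_bond_increments(grown, spec.allow_rings)
    all_smiles = sorted(set().union(*sizes.values()))
    if not all_smiles:
        raise EmptyFixtureError("fixture spec admits no molecules")
    if spec.n_max is not None and len(all_smiles) > spec.n_max:
        rng = np.random.default_rng(spec.seed)
        keep = rng.choice(len(all_smiles), size=spec.n_max, replace=False)
        all_smiles = [all_smiles[i] for i in sorted(keep)]
    return all_smiles


def split_train_test(
    molecules: list[str], ratio: float, seed: int = 0
) -> tuple[list[str], list[str]]:
    """Random disjoint train/test split with |train| = round(ratio * N)."""
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    if len(molecules) < 2:
        raise ValueError("need at least 2 molecules to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(molecules))
    n_train = int(round(ratio * len(molecules)))
    n_train = min(max(n_train, 1), len(molecules) - 1)
    train = [molecules[i] for i in order[:n_train]]
    test = [molecules[i] for i in order[n_train:]]
    return train, test


@dataclass(frozen=True)
class StandardizationResult:
    smiles: str | None
    accepted: bool
    reason: str | None = None


def standardize_chembl_like(smiles: str, max_len: int = 100) -> StandardizationResult:
    """Apply large-corpus cleanup: fragment choice, neutralization, stereo.

    Keeps the fragment with the most heavy atoms (ties broken by molecular
    weight), neutralizes simple protonation-state charges, strips stereo
    information, and rejects molecules whose canonical SMILES exceeds
    ``max_len`` characters. Rejections are data outcomes with reason codes,
    never exceptions.
    """
    mol = Chem.MolFromSmiles(smiles) if isinstance(smiles, str) else None
    if mol is None:
        return StandardizationResult(None, False, "unparseable")
    frags = Chem.GetMolFrags(mol, asMols=True)
    mol = max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Descriptors.MolWt(m)))
    rw = Chem.RWMol(mol)
    for atom in rw.GetAtoms():
        q = atom.GetFormalCharge()
        if q > 0 and atom.GetTotalNumHs() > 0 and atom.GetSymbol() in ("N", "O", "S"):
            atom.SetFormalCharge(q - 1)
            atom.SetNumExplicitHs(max(0, atom.GetNumExplicitHs() - 1))
            atom.SetNoImplicit(False)
        elif q < 0 and atom.GetSymbol() in ("O", "S", "N", "C"):
            atom.SetFormalCharge(q + 1)
            atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
    mol = rw.GetMol()
    try:
        Chem.SanitizeMol(mol)
    except Exception:
        return StandardizationResult(None, False, "sanitize_failed")
    if any(a.GetFormalCharge() != 0 for a in mol.GetAtoms()):
        return StandardizationResult(None, False, "permanent_charge")
    Chem.RemoveStereochemistry(mol)
    canonical = Chem.MolToSmiles(mol)
    if len(canonical) > max_len:
        return StandardizationResult(None, False, "too_long")
    return StandardizationResult(canonical, True, None)


def make_training_pairs(
    molecules: list[str], pairing: PairingMode, seed: int = 0
) -> list[tuple[str, str]]:
    """Build shuffled (input, target) SMILES pairs for a pairing mode.

    ``can2can`` and ``img2can`` yield one identity pair per molecule (the
    image embedding is applied at vectorization time); the enumerated
    modes yield ``n_enum`` pairs per molecule. ``enum2enum`` draws two
    independent enumerations and prefers unequal strings when the molecule
    admits more than one serialization.
    """
    rng = np.random.default_rng(seed)
    pairs: list[tuple[str, str]] = []
    for mol_i, smi in enumerate(molecules):
        can = canonicalize(smi)
        if pairing.mode in ("can2can", "img2can"):
            pairs.append((can, can))
            continue
        sub = int(rng.integers(0, 2**31 - 1))
        if pairing.mode == "can2enum":
            for e in enumerate_smiles(can, pairing.n_enum, seed=sub):
                pairs.append((can, e))
        elif pairing.mode == "enum2can":
            for e in enumerate_smiles(can, pairing.n_enum, seed=sub):
                pairs.append((e, can))
        else:  # enum2enum
            a = enumerate_smiles(can, pairing.n_enum, seed=sub)
            b = enumerate_smiles(can, pairing.n_enum, seed=sub + 1)
            extra = enumerate_smiles(can, 4 * pairing.n_enum, seed=sub + 2)
            for k in range(pairing.n_enum):
                tgt = b[k]
                if tgt == a[k]:
                    for cand in extra:
                        if cand != a[k]:
                            tgt = cand
                            break
                pairs.append((a[k], tgt))
    order = rng.permutation(len(pairs))
    return [pairs[i] for i in order]


# weights of the synthetic structure->property function
PROPERTY_WEIGHTS = {
    "heavy_atoms": 0.4,
    "heteroatoms": 1.5,
    "rings": 0.9,
    "unsaturation": 0.7,
}


def structure_score(smiles: str) -> float:
    """Deterministic additive structure function behind synthetic labels.

    score = 0.4 * heavy atoms + 1.5 * heteroatoms (non-C) + 0.9 * rings
            + 0.7 * unsaturation, where unsaturation sums (bond order - 1)
    over bonds with aromatic bonds counted as order 1.5.
    """
    mol = mol_from_smiles(smiles)
    heavy = mol.GetNumHeavyAtoms()
    hetero = sum(1 for a in mol.GetAtoms() if a.GetSymbol() != "C")
    rings = rdMolDescriptors.CalcNumRings(mol)
    unsat = sum(b.GetBondTypeAsDouble() - 1.0 for b in mol.GetBonds())
    w = PROPERTY_WEIGHTS
    return (
        w["heavy_atoms"] * heavy
        + w["heteroatoms"] * hetero
        + w["rings"] * rings
        + w["unsaturation"] * unsat
    )


def synthetic_property(
    molecules: list[str], noise_sd: float = 0.1, seed: int = 0
) -> np.ndarray:
    """Structure-derived regression labels with Gaussian noise."""
    rng = np.random.default_rng(seed)
    base = np.array([structure_score(s) for s in molecules])
    return base + rng.normal(0.0, noise_sd, size=len(base))


def write_pairs_tsv(path: str | Path, pairs: list[tuple[str, str]]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["input_smiles", "target_smiles"])
        writer.writerows(pairs)


def read_pairs_tsv(path: str | Path) -> list[tuple[str, str]]:
    with open(path) as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        if header[:2] != ["input_smiles", "target_smiles"]:
            raise ValueError(f"unexpected pair-file header: {header}")
        return [(row[0], row[1]) for row in reader]


def read_property_csv(path: str | Path) -> tuple[list[str], list[str], np.ndarray]:
    """Read (ids, smiles, y) from a CSV with columns id,smiles,property."""
    ids, smiles, ys = [], [], []
    with open(path) as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            ids.append(row["id"])
            smiles.append(row["smiles"])
            ys.append(float(row["property"]))
    return ids, smiles, np.asarray(ys)
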