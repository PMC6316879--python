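"""Molecular representations: SMILES, one-hot sequences and image tensors.

This module is the contract between the chemistry side (RDKit molecules)
and the neural-network side (numpy tensors). It provides

* canonicalization and seeded SMILES enumeration (random atom renumbering
  before serialization, the classic data-augmentation trick),
* a :class:`TokenAlphabet` built from a corpus, with one-hot
  vectorization/devectorization,
* the 5-channel 2D image embedding: three atom-type channels from a PCA of
  seven atomic properties, one bond-order channel and one aromaticity
  channel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem

from .atomdata import DEFAULT_PROPERTIES, atomic_properties
from .errors import (
    CellCollisionError,
    EmptyCorpusError,
    GridOverflowError,
    InvalidSmilesError,
    LengthError,
    MissingPropertyError,
    UnknownTokenError,
)

RDLogger.DisableLog("rdApp.*")

PAD = "<pad>"
START = "<start>"
END = "<end>"

# two-character element symbols that must stay single tokens
_TWO_CHAR = ("Cl", "Br")


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES, raising :class:`InvalidSmilesError` on failure."""
    if not isinstance(smiles, str) or not smiles:
        raise InvalidSmilesError(f"not a SMILES string: {smiles!r}")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise InvalidSmilesError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonicalize(smiles: str) -> str:
    """Return RDKit's canonical SMILES for ``smiles``."""
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def try_canonicalize(smiles: str) -> str | None:
    """Canonical SMILES, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles) if smiles else None
    return None if mol is None else Chem.MolToSmiles(mol)


def enumerate_smiles(smiles: str, n: int, seed: int = 0) -> list[str]:
    """Generate ``n`` alternative SMILES serializations of one molecule.

    Atom indices are randomly permuted before non-canonical serialization,
    so each output is a valid SMILES of the same molecule. Outputs may
    repeat (a single atom has only one serialization). Deterministic for a
    fixed seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mol = mol_from_smiles(smiles)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        perm = rng.permutation(mol.GetNumAtoms()).tolist()
        shuffled = Chem.RenumberAtoms(mol, perm)
        out.append(Chem.MolToSmiles(shuffled, canonical=False))
    return out


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES into tokens: characters, except Cl/Br stay whole."""
    tokens = []
    i = 0
    while i < len(smiles):
        if smiles[i : i + 2] in _TWO_CHAR:
            tokens.append(smiles[i : i + 2])
            i += 2
        else:
            tokens.append(smiles[i])
            i += 1
    return tokens


@dataclass(frozen=True)
class TokenAlphabet:
    """Ordered token set shared by the vectorizer and the decoder.

    The first three tokens are always the pad, start and end markers, so
    the pad token has index 0 (one-hot rows of pure padding are column 0).
    """

    tokens: tuple[str, ...]
    pad_token: str = PAD
    start_token: str = START
    end_token: str = END
    _index: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("alphabet tokens must be unique")
        for special in (self.pad_token, self.start_token, self.end_token):
            if special not in self.tokens:
                raise ValueError(f"special token {special!r} missing")
        object.__setattr__(
            self, "_index", {t: i for i, t in enumerate(self.tokens)}
        )

    def __len__(self) -> int:
        return len(self.tokens)

    def index_of(self, token: str) -> int:
        try:
            return self._index[token]
        except KeyError:
            raise UnknownTokenError(f"token {token!r} not in alphabet") from None

    @property
    def pad_index(self) -> int:
        return self.index_of(self.pad_token)

    @property
    def start_index(self) -> int:
        return self.index_of(self.start_token)

    @property
    def end_index(self) -> int:
        return self.index_of(self.end_token)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "tokens": list(self.tokens),
            "pad_token": self.pad_token,
            "start_token": self.start_token,
            "end_token": self.end_token,
        }
        Path(path).write_text(json.dumps(doc, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TokenAlphabet":
        doc = json.loads(Path(path).read_text())
        return cls(
            tokens=tuple(doc["tokens"]),
            pad_token=doc["pad_token"],
            start_token=doc["start_token"],
            end_token=doc["end_token"],
        )


def build_alphabet(corpus: list[str]) -> TokenAlphabet:
    """Build a :class:`TokenAlphabet` covering every SMILES in ``corpus``.

    Token order is [pad, start, end] followed by the observed tokens in
    sorted order, so the alphabet is stable for a fixed corpus.
    """
    if not corpus:
        raise EmptyCorpusError("cannot build an alphabet from an empty corpus")
    observed: set[str] = set()
    for smi in corpus:
        observed.update(tokenize(smi))
    tokens = (PAD, START, END) + tuple(sorted(observed))
    return TokenAlphabet(tokens=tokens)


def enumeration_closed_alphabet(corpus: list[str]) -> TokenAlphabet:
    """Alphabet covering every enumerated serialization of the corpus.

    Non-canonical serializations of a molecule can use tokens its canonical
    SMILES avoids: branch parentheses (any atom of degree >= 2 can become a
    branching point) and extra ring-closure digits (up to the molecule's
    cyclomatic number of simultaneously open ring bonds). Those are added
    analytically on top of the observed corpus tokens, so encoders trained
    on canonical SMILES can still consume enumerated inputs.
    """
    if not corpus:
        raise EmptyCorpusError("cannot build an alphabet from an empty corpus")
    observed: set[str] = set()
    max_rings = 0
    needs_parens = False
    for smi in corpus:
        observed.update(tokenize(smi))
        mol = mol_from_smiles(smi)
        rings = mol.GetNumBonds() - mol.GetNumAtoms() + 1
        max_rings = max(max_rings, rings)
        if mol.GetNumAtoms() >= 3:
            needs_parens = True
    if needs_parens:
        observed.update("()")
    observed.update(str(d) for d in range(1, max_rings + 1))
    tokens = (PAD, START, END) + tuple(sorted(observed))
    return TokenAlphabet(tokens=tokens)


def vectorize(smiles: str, alphabet: TokenAlphabet, maxlen: int) -> np.ndarray:
    """One-hot encode ``smiles`` as a (maxlen, V) matrix.

    Layout: start token, SMILES tokens, end token, right-padded with the
    pad token. Every row is exactly one-hot.
    """
    toks = tokenize(smiles)
    if len(toks) + 2 > maxlen:
        raise LengthError(
            f"SMILES of {len(toks)} tokens does not fit in maxlen={maxlen}"
        )
    idx = [alphabet.start_index]
    idx += [alphabet.index_of(t) for t in toks]
    idx.append(alphabet.end_index)
    idx += [alphabet.pad_index] * (maxlen - len(idx))
    mat = np.zeros((maxlen, len(alphabet)), dtype=np.float64)
    mat[np.arange(maxlen), idx] = 1.0
    return mat


def token_indices(smiles: str, alphabet: TokenAlphabet, maxlen: int) -> np.ndarray:
    """Integer-index version of :func:`vectorize` (same layout)."""
    toks = tokenize(smiles)
    if len(toks) + 2 > maxlen:
        raise LengthError(
            f"SMILES of {len(toks)} tokens does not fit in maxlen={maxlen}"
        )
    idx = [alphabet.start_index]
    idx += [alphabet.index_of(t) for t in toks]
    idx.append(alphabet.end_index)
    idx += [alphabet.pad_index] * (maxlen - len(idx))
    return np.asarray(idx, dtype=np.int64)


def devectorize(seq: np.ndarray, alphabet: TokenAlphabet) -> str:
    """Invert :func:`vectorize`: argmax rows back to the SMILES string."""
    idx = np.asarray(seq).argmax(axis=1)
    tokens = [alphabet.tokens[i] for i in idx]
    if tokens and tokens[0] == alphabet.start_token:
        tokens = tokens[1:]
    out = []
    for t in tokens:
        if t == alphabet.end_token or t == alphabet.pad_token:
            break
        out.append(t)
    return "".join(out)


@dataclass(frozen=True)
class AtomChannelTable:
    """Element -> three atom-type channel values in [0, 1].

    The values are min-max scaled scores of the first three principal
    components of seven atomic properties over the covered element set.
    """

    mapping: dict[str, tuple[float, float, float]]

    def channels(self, element: str) -> tuple[float, float, float]:
        try:
            return self.mapping[element]
        except KeyError:
            raise MissingPropertyError(
                f"element {element!r} not in atom channel table"
            ) from None

    def __contains__(self, element: str) -> bool:
        return element in self.mapping


def atom_channel_table(
    elements: list[str],
    properties: tuple[str, ...] = DEFAULT_PROPERTIES,
) -> AtomChannelTable:
    """PCA-based atom-type encoding over an element set.

    The property matrix (elements x properties) is column-standardized,
    decomposed with covariance PCA, and the first three component scores
    are min-max scaled to [0, 1] per component. Component signs follow the
    convention that the loading of largest magnitude is positive, which
    makes the table deterministic.
    """
    if len(elements) < 4:
        raise ValueError("need at least 4 elements for a 3-component PCA")
    rows = np.array(
        [[atomic_properties(el)[p] for p in properties] for el in elements],
        dtype=np.float64,
    )
    mean = rows.mean(axis=0)
    sd = rows.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    z = (rows - mean) / sd
    cov = np.cov(z, rowvar=False, ddof=1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1][:3]
    components = eigvec[:, order]  # (n_props, 3)
    # deterministic sign: largest-|loading| entry positive per component
    for k in range(components.shape[1]):
        j = np.argmax(np.abs(components[:, k]))
        if components[j, k] < 0:
            components[:, k] = -components[:, k]
    scores = z @ components  # (n_elements, 3)
    lo, hi = scores.min(axis=0), scores.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scaled = (scores - lo) / span
    mapping = {el: tuple(float(v) for v in scaled[i]) for i, el in enumerate(elements)}
    return AtomChannelTable(mapping=mapping)


_BOND_ORDER = {
    Chem.BondType.SINGLE: 1.0,
    Chem.BondType.DOUBLE: 2.0,
    Chem.BondType.TRIPLE: 3.0,
    Chem.BondType.AROMATIC: 1.5,
}


def embed_image(
    smiles: str,
    table: AtomChannelTable,
    height: int = 80,
    width: int = 80,
    resolution: float = 0.5,
    rotation: float | str = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Rasterize a molecule to an (height, width, 5) tensor.

    Channels 0-2 carry the atom-type PCA values at atom cells, channel 3
    the bond order (aromatic bonds as 1.5) at points along each bond, and
    channel 4 flags cells occupied by aromatic atoms. 2D coordinates are
    centered on the grid and rotated by ``rotation`` degrees (or a seeded
    uniform draw in [-180, 180] when ``rotation="random"``) before
    discretization.
    """
    mol = mol_from_smiles(smiles)
    AllChem.Compute2DCoords(mol)
    conf = mol.GetConformer()
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y]
         for i in range(mol.GetNumAtoms())]
    )
    coords -= coords.mean(axis=0)
    if rotation == "random":
        theta = np.deg2rad(np.random.default_rng(seed).uniform(-180.0, 180.0))
    else:
        theta = np.deg2rad(float(rotation))
    rot = np.array(
        [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
    )
    coords = coords @ rot.T

    def cell(xy):
        # +0.5 puts the molecular centroid at the center of a cell rather
        # than on a cell-boundary corner
        col = int(np.floor(xy[0] / resolution + width / 2.0 + 0.5))
        row = int(np.floor(xy[1] / resolution + height / 2.0 + 0.5))
        return row, col

    grid = np.zeros((height, width, 5), dtype=np.float64)
    occupied: dict[tuple[int, int], int] = {}
    for i, atom in enumerate(mol.GetAtoms()):
        row, col = cell(coords[i])
        if not (0 <= row < height and 0 <= col < width):
            raise GridOverflowError(
                f"atom {i} of {smiles!r} falls outside the {height}x{width} grid"
            )
        if (row, col) in occupied:
            raise CellCollisionError(
                f"atoms {occupied[(row, col)]} and {i} of {smiles!r} share a cell"
            )
        occupied[(row, col)] = i
        grid[row, col, 0:3] = table.channels(atom.GetSymbol())
        if atom.GetIsAromatic():
            grid[row, col, 4] = 1.0

    for bond in mol.GetBonds():
        a = coords[bond.GetBeginAtomIdx()]
        b = coords[bond.GetEndAtomIdx()]
        order = _BOND_ORDER[bond.GetBondType()]
        length = float(np.linalg.norm(b - a))
        # midpoint plus evenly spaced interior points, ~half-pixel spacing
        n_pts = max(1, int(np.ceil(length / (resolution / 2.0))) - 1)
        for t in np.linspace(0.0, 1.0, n_pts + 2)[1:-1]:
            row, col = cell(a + t * (b - a))
            if not (0 <= row < height and 0 <= col < width):
                raise GridOverflowError(
                    f"bond point of {smiles!r} falls outside the grid"
                )
            if (row, col) not in occupied:
                grid[row, col, 3] = max(grid[row, col, 3], order)
    return grid


def read_smiles_file(path: str | Path) -> list[str]:
    """Read SMILES from plain text, one per line, optional leading id tab."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        out.append(fields[1] if len(fields) > 1 else fields[0])
    return out


def write_smiles_file(path: str | Path, smiles: list[str]) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")
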