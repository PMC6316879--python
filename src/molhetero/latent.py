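"""Latent-space structure: similarity metrics, correlations, challenge, NN.

Three pairwise similarity measures are compared: the latent-space
similarity (negative natural log of the Euclidean distance between code
vectors), the circular Morgan fingerprint Tanimoto similarity (radius 2,
2048 bits), and the global pairwise SMILES alignment score. Squared
Pearson correlations between the latent similarity and the other two
quantify whether the latent space organizes by molecular graph or by
SMILES string.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from Bio import Align
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats
from sklearn.decomposition import PCA

from .errors import DegenerateDataError, DimensionError
from .representations import canonicalize, enumerate_smiles, mol_from_smiles
from .model import Encoder, encode, encode_strings

#: distance floor making the self-pair latent similarity finite
DISTANCE_FLOOR = 1e-12


@dataclass(frozen=True)
class AlignmentParams:
    """Global-alignment scoring: +1 match, -1 mismatch, -0.5 gap opening,
    -0.05 gap extension (extensions are penalized less than openings)."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -0.5
    gap_extend: float = -0.05

    def __post_init__(self):
        if self.gap_extend < self.gap_open:
            raise ValueError("gap_extend must be >= gap_open (less penalized)")
        if self.match <= self.mismatch:
            raise ValueError("match score must exceed mismatch score")


@dataclass(frozen=True)
class SimilarityTriple:
    """The three similarity readings for one ordered molecule pair."""

    latent_sim: float
    fp_sim: float
    seq_score: float


@dataclass
class ChallengeResult:
    """Enumeration-challenge output: 2D projections and latent-space spread."""

    projections: dict[str, np.ndarray]  # molecule -> (n_enum, 2) PCA scores
    spreads: dict[str, float]  # molecule -> mean pairwise latent distance
    background_projection: np.ndarray  # (n_background, 2)


def latent_similarity(v1: np.ndarray, v2: np.ndarray) -> float:
    """-ln(Euclidean distance), floored at 1e-12 so self-pairs are finite."""
    v1 = np.asarray(v1, dtype=np.float64)
    v2 = np.asarray(v2, dtype=np.float64)
    if v1.shape != v2.shape:
        raise DimensionError(f"latent shapes differ: {v1.shape} vs {v2.shape}")
    dist = float(np.linalg.norm(v1 - v2))
    return -float(np.log(max(dist, DISTANCE_FLOOR)))


_MORGAN = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048)


def morgan_fingerprint(smiles: str):
    """2048-bit hashed Morgan fingerprint, radius 2."""
    return _MORGAN.GetFingerprint(mol_from_smiles(smiles))


def fingerprint_similarity(m1: str, m2: str) -> float:
    """Tanimoto similarity of radius-2 Morgan fingerprints (2048 bits)."""
    return float(DataStructs.TanimotoSimilarity(
        morgan_fingerprint(m1), morgan_fingerprint(m2)))


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = params.match
    aligner.mismatch_score = params.mismatch
    aligner.open_gap_score = params.gap_open
    aligner.extend_gap_score = params.gap_extend
    return aligner


def alignment_score(s1: str, s2: str,
                    params: AlignmentParams = AlignmentParams()) -> float:
    """Optimal global pairwise alignment score between two strings.

    A gap of length k costs gap_open + (k-1) * gap_extend; end gaps are
    scored like internal ones.
    """
    if not s1 or not s2:
        raise ValueError("alignment requires non-empty strings")
    return float(_aligner(params).score(s1, s2))


def similarity_triples(
    reference: str,
    testset: list[str],
    encoder: Encoder,
    params: AlignmentParams = AlignmentParams(),
) -> list[SimilarityTriple]:
    """All three similarities between a reference molecule and a test set.

    The sequence metric aligns the decoder-target-form canonical SMILES of
    the molecules; the latent metric uses the encoder's code vectors.
    """
    ref_can = canonicalize(reference)
    others = [canonicalize(m) for m in testset if canonicalize(m) != ref_can]
    vecs = encode(encoder, [ref_can] + others, representation="canonical")
    triples = []
    for i, smi in enumerate(others):
        triples.append(SimilarityTriple(
            latent_sim=latent_similarity(vecs[0], vecs[i + 1]),
            fp_sim=fingerprint_similarity(ref_can, smi),
            seq_score=alignment_score(ref_can, smi, params),
        ))
    return triples


def similarity_correlations(
    reference: str,
    testset: list[str],
    encoder: Encoder,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[float, float]:
    """(R^2 fingerprint, R^2 sequence) against the latent similarity.

    R^2 is the squared Pearson correlation over reference-vs-testset pairs
    (self-pairs excluded).
    """
    triples = similarity_triples(reference, testset, encoder, params)
    if len(triples) < 3:
        raise DegenerateDataError("need at least 3 non-reference molecules")
    lat = np.array([t.latent_sim for t in triples])
    fp = np.array([t.fp_sim for t in triples])
    seq = np.array([t.seq_score for t in triples])
    for arr, name in ((lat, "latent"), (fp, "fingerprint"), (seq, "sequence")):
        if np.ptp(arr) == 0:
            raise DegenerateDataError(f"zero variance in {name} metric")
    r2_fp = float(stats.pearsonr(lat, fp).statistic ** 2)
    r2_seq = float(stats.pearsonr(lat, seq).statistic ** 2)
    return r2_fp, r2_seq


def mean_similarity_correlations(
    references: list[str],
    testset: list[str],
    encoder: Encoder,
    params: AlignmentParams = AlignmentParams(),
) -> tuple[float, float]:
    """Multi-reference average of :func:`similarity_correlations`."""
    pairs = [similarity_correlations(r, testset, encoder, params)
             for r in references]
    arr = np.array(pairs)
    return float(arr[:, 0].mean()), float(arr[:, 1].mean())


def enumeration_challenge(
    encoder: Encoder,
    molecules: list[str],
    n_enum: int,
    background: list[str],
    seed: int = 0,
) -> ChallengeResult:
    """Project enumerated-SMILES latents onto a background-fitted 2D PCA.

    The PCA is fitted on the background (test-set) latents only; the
    challenge molecules' enumerations are transformed with those loadings.
    The reported spread is the mean pairwise Euclidean distance between a
    molecule's enumeration latents in the full latent space, not the 2D
    projection.
    """
    if len(background) < 2:
        raise ValueError("background must contain at least 2 molecules")
    if n_enum < 2:
        raise ValueError("n_enum must be >= 2 to measure spread")
    bg_latents = encode(encoder, background, representation="canonical")
    pca = PCA(n_components=2)
    bg_proj = pca.fit_transform(bg_latents)
    projections: dict[str, np.ndarray] = {}
    spreads: dict[str, float] = {}
    rng = np.random.default_rng(seed)
    for smi in molecules:
        can = canonicalize(smi)
        enums = enumerate_smiles(can, n_enum, seed=int(rng.integers(2**31 - 1)))
        latents = encode_strings(encoder, enums)
        projections[can] = pca.transform(latents)
        diffs = latents[:, None, :] - latents[None, :, :]
        dists = np.sqrt((diffs**2).sum(axis=-1))
        iu = np.triu_indices(len(enums), k=1)
        spreads[can] = float(dists[iu].mean())
    return ChallengeResult(projections=projections, spreads=spreads,
                           background_projection=bg_proj)


def nearest_neighbors(query: str, encoder: Encoder, library: list[str],
                      k: int) -> list[str]:
    """k library molecules most similar to the query in latent space.

    Sorted by descending latent similarity; ties keep library order.
    """
    if not library:
        raise ValueError("library must be non-empty")
    if k > len(library):
        raise ValueError("k exceeds library size")
    vecs = encode(encoder, [query] + list(library), representation="canonical")
    sims = [latent_similarity(vecs[0], v) for v in vecs[1:]]
    order = sorted(range(len(library)), key=lambda i: (-sims[i], i))
    return [library[i] for i in order[:k]]


def write_similarity_csv(path: str | Path, ref_id: str,
                         mol_ids: list[str],
                         triples: list[SimilarityTriple]) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["ref_id", "mol_id", "latent_sim", "fp_sim", "seq_score"])
        for mol_id, t in zip(mol_ids, triples):
            writer.writerow([ref_id, mol_id,
                             f"{t.latent_sim:.6f}", f"{t.fp_sim:.6f}",
                             f"{t.seq_score:.6f}"])


def write_challenge_csv(path: str | Path, result: ChallengeResult) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["mol_id", "enum_idx", "pc1", "pc2"])
        for mol, proj in result.projections.items():
            for i, (pc1, pc2) in enumerate(proj):
                writer.writerow([mol, i, f"{pc1:.6f}", f"{pc2:.6f}"])


def write_spread_json(path: str | Path, result: ChallengeResult) -> None:
    Path(path).write_text(json.dumps(result.spreads, indent=1))
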