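"""Molecular representations: enumeration, one-hot sequences, image tensors.

Builds the three input/output representations the encoders and decoders
work with, for a single molecule (toluene).
"""

import numpy as np

from molhetero.representations import (
    atom_channel_table,
    build_alphabet,
    canonicalize,
    devectorize,
    embed_image,
    enumerate_smiles,
    vectorize,
)

toluene = canonicalize("Cc1ccccc1")
print(f"canonical SMILES: {toluene}")

# SMILES enumeration: random atom renumbering before serialization gives
# alternative strings that all denote the same molecule
variants = enumerate_smiles(toluene, n=5, seed=42)
print("five enumerated serializations:")
for v in variants:
    assert canonicalize(v) == toluene
    print("   ", v)

# one-hot sequence encoding against a corpus-derived token alphabet
corpus = [toluene] + variants
alphabet = build_alphabet(corpus)
mat = vectorize(toluene, alphabet, maxlen=14)
print(f"one-hot matrix: {mat.shape} (positions x alphabet of "
      f"{len(alphabet)} tokens), round-trips to {devectorize(mat, alphabet)!r}")

# 5-channel image embedding: 3 atom-type channels are min-max scaled PCA
# scores of seven atomic properties; channel 3 is bond order, channel 4
# flags aromatic atoms
table = atom_channel_table(["C", "N", "O", "F", "S", "Cl"])
img = embed_image(toluene, table, height=48, width=48, resolution=0.5,
                  rotation=0.0)
print(f"image tensor: {img.shape}, aromatic atom cells: "
      f"{int((img[:, :, 4] == 1).sum())} (the 6 ring carbons), "
      f"bond-channel cells: {int((img[:, :, 3] > 0).sum())}")
print(f"carbon atom channels: {np.round(table.channels('C'), 3)}")
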