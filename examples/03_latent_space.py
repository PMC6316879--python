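"""Latent-space analytics: similarity metrics, correlations, challenge, NN.

Trains a small autoencoder, then (a) correlates latent similarity with the
fingerprint and SMILES-alignment metrics, (b) runs the SMILES-enumeration
challenge, and (c) retrieves latent-space nearest neighbours.
"""

import numpy as np

from molhetero import datasets, latent, model, nn, workflows
from molhetero.workflows import ExperimentConfig

nn.set_default_dtype(np.float32)

cfg = ExperimentConfig(max_heavy_atoms=4, epochs=800, batch_size=64,
                       initial_lr=0.01, lr_patience=50, restore_best=False,
                       seed=0, pairing_mode="can2can")
molecules = workflows.load_molecules(cfg)
train_set, test_set = datasets.split_train_test(molecules, 0.9, seed=0)
trained, _ = workflows.build_and_train(cfg, train_set, test_set)
encoder, _, _ = model.split_models(trained)

# three similarity metrics against one reference molecule
reference = test_set[0]
r2_fp, r2_seq = latent.similarity_correlations(reference, train_set, encoder)
print(f"reference {reference}: R^2(latent vs fingerprint) = {r2_fp:.2f}, "
      f"R^2(latent vs sequence alignment) = {r2_seq:.2f}")
print("a canonical-SMILES decoder organizes its latent space around the "
      "strings, so the sequence R^2 tends to be the larger of the two")

# enumeration challenge: how tightly do a molecule's alternative SMILES
# cluster in latent space?
challenge = latent.enumeration_challenge(encoder, test_set[:3], n_enum=8,
                                         background=test_set, seed=0)
for mol, spread in challenge.spreads.items():
    print(f"   {mol:>8s}: latent spread over 8 enumerations = {spread:.2f}")
print("enumeration-trained encoders shrink these spreads (see the tests)")

# nearest neighbours of a query molecule in latent space
neighbours = latent.nearest_neighbors("CCO", encoder, train_set, k=5)
print("latent-space neighbours of CCO:", ", ".join(neighbours))
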