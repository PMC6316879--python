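"""Train a canonical-to-canonical SMILES autoencoder and decode.

Uses the exhaustive <=4-heavy-atom fixture set (571 molecules); the run
takes about a minute on one CPU. The same code scales to the full <=5-atom
study in scripts/acceptance.py.
"""

import numpy as np

from molhetero import datasets, model, nn, workflows
from molhetero.workflows import ExperimentConfig

nn.set_default_dtype(np.float32)  # single precision halves the runtime

cfg = ExperimentConfig(max_heavy_atoms=4, epochs=800, batch_size=64,
                       initial_lr=0.01, lr_patience=50, restore_best=False,
                       seed=0)
molecules = workflows.load_molecules(cfg)
train_set, test_set = datasets.split_train_test(molecules, 0.9, seed=0)
print(f"{len(molecules)} molecules: {len(train_set)} train, "
      f"{len(test_set)} held out")

trained, history = workflows.build_and_train(cfg, train_set, test_set)
print(f"training loss {history.train_loss[0]:.3f} -> "
      f"{history.train_loss[-1]:.4f} over {len(history.train_loss)} epochs; "
      f"final held-out loss {history.val_loss[-1]:.3f}")

# split into deployment parts: encoder, state initializer, stateful decoder
encoder, state_init, step_decoder = model.split_models(trained)
decoded, reports = workflows.greedy_reconstruction(trained, test_set)
exact = sum(1 for r in reports if r.valid and r.same_molecule)
print(f"greedy reconstruction of held-out molecules: {exact}/{len(test_set)} "
      "exact")
for smi, out in list(zip(test_set, decoded))[:5]:
    marker = "" if out == smi else "   <- miss"
    print(f"   {smi:>8s} -> {out}{marker}")
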