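# Methods

## The models

`molhetero` builds sequence-to-sequence neural translators between
representations of the same molecule. The encoder reads one representation
(a one-hot-encoded SMILES string, or a 2D image tensor of the molecule)
and compresses it into a fixed-length latent vector; the decoder
reconstructs a SMILES string from that vector, one token at a time. When
input and output are the same canonical SMILES the model is an
autoencoder; when they differ — canonical to enumerated SMILES, enumerated
to canonical, image to canonical — it is a *heteroencoder*, forced to
extract the molecule behind the serialization rather than the string
itself.

Sequence encoder: one or two LSTM layers read the one-hot input in batch
mode; the hidden state H and cell state C of the last layer, taken at each
sequence's own end-token position, are concatenated and passed through a
dense layer with ReLU activation — the *code layer*, whose activations are
the latent vector (hence non-negative). Gathering the states at the end
token (rather than after running through the right padding) makes the code
invariant to the padding length by construction; the bidirectional encoder
keeps the conventional final states of both directions.
Decoder: one ReLU dense layer per state per decoder LSTM layer maps the
code back to initial H and C states (two dense layers for a one-layer
decoder, four for two layers); the LSTM stack then runs under teacher
forcing and a softmax dense layer sized to the token alphabet emits
next-token distributions.

Variants mirror the reference architectures:

| variant | encoder | decoder | code |
|---|---|---|---|
| `seq1` | 1×64 LSTM | 1×64 LSTM | 64 |
| `seq2` | 2×128 LSTM | 2×128 LSTM | 64 |
| `chembl` | 2 bidirectional ×128/direction | 2×256 | 256, batch-norm after each dense activation |
| `img2seq` | inception-style CNN | 1×64 LSTM | 64 |

The inception encoder stacks seven modules — an initial module (1×1→3×3,
1×1→5×5 and lone-1×1 towers), then three pairs of a standard module
(adds a half-width 1×1→7×7 tower and a maxpool→1×1 tower, stride 1) and a
reduction module (no 7×7 tower, stride 2) — with 32 kernels per tower,
followed by flatten, dropout 0.2 and the ReLU code dense.

After training, `split_models` produces the three deployment pieces with
copied weights: the encoder (molecules → latent vectors), the state
initializer (latent vector → initial decoder states) and a stateful
single-step decoder used for greedy and multinomial generation. The state
concatenation order is fixed as [H; C] throughout; any fixed order is
equivalent, but it must be frozen for the split-model identity to hold.

## The neural-network engine

No deep-learning framework is a dependency: the networks run on a small
reverse-mode automatic-differentiation engine over numpy arrays
(`molhetero.nn`). The LSTM forward/backward pass is fused into a single
graph node with hand-written backpropagation through time, which is what
makes CPU training of the study-sized models practical. All gradients are
pinned by central-difference numerical checks in the test suite. Kernel
initialization is Glorot-uniform, recurrent kernels are orthogonal
per gate block, and forget-gate biases start at 1 — the standard LSTM
choices. The engine computes in float64 by default; the large training
runs (acceptance script) switch to float32 for speed. Runs are
single-threaded and deterministic for a fixed seed.

## Training schedule

Categorical cross-entropy under teacher forcing, averaged over non-pad
target positions only (an unmasked average inflates apparent convergence
on short molecules), optimized with Adam. Gradients are clipped to global
norm 5. The held-out split's loss is monitored every epoch: the learning
rate is halved after `lr_patience` epochs without improvement (never below
`min_lr`, default `initial_lr`/16 — without a floor the plateau scheduler
can anneal the rate to zero long before the decoder's output distributions
saturate), optional early stopping, and the best-validation-loss weights
are restored at the end (checkpointing). Because unidirectional
encoders are padding-invariant, training batches are length-bucketed (a
fresh shuffle stably sorted by length each epoch) and trimmed to the
longest sequence in the batch — identical numerics on the non-pad
positions at roughly half the cost. Desk-scale defaults are batch 64,
100 epochs, initial rate 0.005; the convergence runs in the acceptance
script use batch 256, 1200 epochs, initial rate 0.01 on the full fixture
set with the final-weights protocol. Small-data runs need many more epochs
than large-corpus training because convergence is governed by optimizer
steps, not passes over the data.

## Synthetic fixture data

`datasets.generate_fixture_molecules` enumerates **all** valence-valid
connected molecules up to a heavy-atom budget over a small element set
(valence caps C4/N3/O2/F1): molecules grow atom-by-atom, and each size
class is closed under single bond additions and bond-order raises, with
canonical-SMILES deduplication. Up to 5 heavy atoms over {C,N,O} this
yields 4141 molecules. The set emulates the *fully enumerated* character
of the GDB databases at desk scale: every held-out molecule has close
structural neighbours in training, which is the regime in which these
autoencoders reach near-perfect reconstruction. What it does not emulate:
drug-like size (≤5 vs 8+ heavy atoms), chemical-stability filtering (the
set contains exotica like pentazole tautomers or O=O that curated
databases exclude), stereochemistry, and charge states. Passing tests at
this scale demonstrate the mechanics and the qualitative orderings, not
ChEMBL-scale reconstruction rates.

Synthetic QSAR labels are a documented additive structure function —
0.4·(heavy atoms) + 1.5·(heteroatoms) + 0.9·(rings) + 0.7·(unsaturation,
Σ(bond order − 1) with aromatic = 1.5) — plus Gaussian noise (default SD
0.1). The function is graph-derived, so latent vectors of a converged
encoder can predict it; it has no biological meaning.

## Tokenization and vectorization

Character-level tokens except the two-character elements Cl and Br;
the alphabet is `[pad, start, end]` + sorted observed tokens, so pad is
always index 0. Sequences are `[start] + tokens + [end]`, right-padded;
the decoder input is the sequence shifted by one (teacher forcing).
Encoders trained on canonical SMILES are later fed *enumerated* SMILES
(the enumeration challenge), so `enumeration_closed_alphabet` adds branch
parentheses and ring-closure digits up to the corpus's maximal cyclomatic
number analytically, and the sequence-length budget is probed with sample
enumerations plus headroom.

The image embedding rasterizes RDKit 2D coordinates (centroid centered on
a cell, optional seeded rotation in ±180°) onto an 80×80 grid at
0.5 Å/pixel by default. Channels 0–2 hold the element's atom-type values:
min-max-scaled scores of the first three principal components of seven
atomic reference properties (dipole polarizability, electron affinity,
electronegativity, vdW radius, atomic volume, softness, hardness; values
embedded as a constants table, hardness/softness derived from ionization
energy and electron affinity). PCA is computed on column-standardized
properties with a deterministic sign convention (largest-magnitude loading
positive). Channel 3 writes the bond order (aromatic = 1.5) at the
midpoint and evenly spaced interior points of each bond (~half-pixel
spacing); channel 4 flags aromatic-atom cells. Atom cell collisions and
grid overflow raise rather than silently overwrite.

## Latent-space metrics

* latent similarity: −ln(Euclidean distance), with the distance floored at
  1e-12 so self-pairs are finite. The log base only scales the metric and
  cannot change the correlations; natural log is used.
* fingerprint similarity: Tanimoto over hashed Morgan fingerprints,
  radius 2, 2048 bits.
* sequence similarity: optimal global pairwise alignment score with match
  +1, mismatch −1, gap opening −0.5, gap extension −0.05 (a length-k gap
  costs open + (k−1)·extend, end gaps included), computed with Biopython's
  PairwiseAligner and cross-checked in the tests against an exhaustive
  enumeration of all alignments.

R² values are squared Pearson correlations between the latent similarity
and each of the other two, over pairs of one reference molecule with a
comparison set (single-reference reading; a multi-reference average is
provided as `mean_similarity_correlations`). The sequence metric aligns
the canonical SMILES of the molecules. In the enumeration challenge the
2-component PCA is fitted on the background (test-set) latents only and
the challenge enumerations are projected with those loadings; the reported
spread is the mean pairwise Euclidean distance in the full latent space,
not in the 2D projection.

## Error taxonomy and sampling statistics

A decoded string is *invalid* if RDKit cannot parse it; otherwise molecule
identity is canonical-SMILES equality. Wrong molecules are localized by
three comparisons: the generalized scaffold — implemented as the generic
(all atoms carbon-like, all bonds single) Bemis–Murcko skeleton computed
on the whole molecule with side chains retained, so scaffold equality is
heavy-atom-graph isomorphism; the Hill sum formula (implicit hydrogens
included); and a bond census counting single/double/triple/aromatic bonds
with aromatic bonds as their own class. The "including side-chains"
generalization is one documented reading of an ambiguous recipe and is
isolated behind `generalized_scaffold` so it can be swapped. Sampling
statistics count invalid samples in n but exclude them from molecule-level
tallies; the mean fingerprint similarity includes correct-molecule
samples (a fully-correct run scores 1.0) and is averaged after sorting so
the statistic is exactly order-invariant.

Multinomial sampling renormalizes pₜ^(1/T) at each step; T ≤ 1e-6 falls
back to argmax, making the zero-temperature limit exactly greedy decoding.
The temperature-application form (renormalized power) is an assumption
pinned by tests.

## QSAR protocol

Features: 1024-bit ECFP4 (Morgan radius 2) or encoder latent vectors.
The feed-forward regressor's hyperparameters (input dropout, width, L2,
maxnorm, initializer, batch-norm, ReLU/SeLU, dropout, depth 1–6, learning
rate, one of four optimizers) are searched with seeded random sampling —
log-uniform where a bound spans ≥2 orders of magnitude (L2, learning
rate), uniform otherwise — scored by 3-fold CV MSE on the training set;
a TPE-style optimizer can be plugged in as a callable. The selected
configuration is reused unchanged for latent features. Test metrics come
from averaging the 10 fold models of a 10-fold CV fit (fold seeds derive
from fold membership, making the ensemble order-invariant); R² is the
squared Pearson correlation of ensemble predictions with the test labels.
Targets are z-scored inside each fit and predictions unscaled.

## Problem sizes used by the test suite and acceptance script

The acceptance script trains the seq1 can2can model on the full
≤5-heavy-atom set (4141 molecules, 90/10 split) for 1200 epochs at
batch 256 with the final-weights protocol — the smallest setting we found
that reaches the saturated sampling regime (1000 multinomial samples from
a held-out latent collapsing to a single SMILES). The test suite uses the ≤3-atom set (93 molecules) for
unit-level model tests and the ≤4-atom set (571 molecules) with shorter
schedules for the qualitative-ordering checks; those runs are converged
enough for orderings but not for perfect reconstruction, which is why the
quantitative reconstruction checks live in the acceptance run.

## Known limitations

* Desk-scale molecules (≤5 heavy atoms) — reconstruction rates and R²
  magnitudes are not comparable to large-corpus training, only the
  qualitative behaviour is.
* The numpy engine is single-core; ChEMBL-scale corpora are out of reach.
* The standardizer implements only the four stated cleanup steps (largest
  organic fragment, protonation-state neutralization, stereo removal,
  length cap); permanent charges are rejected with a reason code rather
  than transformed.
* No variational/adversarial regularization of the code layer, no beam
  search, no GRU cells, no 3D conformers, no stereochemistry-aware
  enumeration.
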