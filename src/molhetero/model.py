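"""Encoder -> code layer -> decoder networks over molecular representations.

The sequence-to-sequence architecture: the encoder LSTM reads a one-hot
SMILES, its final hidden (H) and memory (C) states are concatenated and
compressed by a ReLU dense layer (the code layer, the latent vector). Two
ReLU dense layers per decoder LSTM layer map the code back to initial H
and C states, and the decoder LSTM predicts the target sequence under
teacher forcing through a softmax output layer sized to the alphabet.

Variants
--------
``seq1``    1 x 64 LSTM cells on both sides, 64-d code.
``seq2``    2 x 128 LSTM cells on both sides, 64-d code.
``chembl``  encoder 2 bidirectional layers of 128 cells per direction,
            decoder 2 x 256, 256-d code, batch normalization after every
            non-linear dense activation.
``img2seq`` inception-style convolutional encoder over the 5-channel 2D
            molecule image, seq1-style decoder.

After training, :func:`split_models` produces the three deployment pieces:
the encoder, the state initializer, and a stateful single-step decoder
whose weights are copied from the full model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor
from .errors import (
    ConfigError,
    DivergenceError,
    NotTrainedError,
    StateError,
)
from .representations import (
    TokenAlphabet,
    atom_channel_table,
    canonicalize,
    embed_image,
    enumerate_smiles,
    token_indices,
    vectorize,
)

_VARIANTS = ("seq1", "seq2", "chembl", "img2seq")


@dataclass
class HeteroencoderConfig:
    """Architecture and training-schedule parameters.

    The per-variant layer/cell counts follow the reference architectures;
    ``encoder_cells``/``decoder_cells`` can scale them down for desk-size
    experiments without changing the topology.
    """

    variant: str = "seq1"
    code_dim: int | None = None  # default by variant: 64 (seq/img), 256 (chembl)
    batch_size: int = 64
    epochs: int = 100
    initial_lr: float = 0.005
    lr_patience: int = 5
    min_lr: float | None = None  # default: initial_lr / 16
    early_stop_patience: int | None = None
    # restore the best-validation checkpoint at the end (large-corpus
    # protocol); False keeps the final weights, whose output distributions
    # are sharper after long small-corpus runs
    restore_best: bool = True
    seed: int = 0
    encoder_cells: int | None = None
    decoder_cells: int | None = None
    grad_clip: float = 5.0
    # image-encoder parameters (img2seq only)
    image_height: int = 80
    image_width: int = 80
    resolution: float = 0.5
    inception_kernels: int = 32
    image_dropout: float = 0.2
    image_elements: tuple[str, ...] = ("C", "N", "O", "F", "S", "Cl")

    def __post_init__(self):
        if self.variant not in _VARIANTS:
            raise ConfigError(f"variant must be one of {_VARIANTS}")
        if self.code_dim is None:
            self.code_dim = 256 if self.variant == "chembl" else 64
        if self.code_dim <= 0 or self.batch_size <= 0:
            raise ConfigError("code_dim and batch_size must be positive")

    @property
    def enc_layers(self) -> int:
        return {"seq1": 1, "seq2": 2, "chembl": 2, "img2seq": 0}[self.variant]

    @property
    def dec_layers(self) -> int:
        return {"seq1": 1, "seq2": 2, "chembl": 2, "img2seq": 1}[self.variant]

    @property
    def enc_cells(self) -> int:
        if self.encoder_cells is not None:
            return self.encoder_cells
        return {"seq1": 64, "seq2": 128, "chembl": 128, "img2seq": 0}[self.variant]

    @property
    def dec_cells(self) -> int:
        if self.decoder_cells is not None:
            return self.decoder_cells
        return {"seq1": 64, "seq2": 128, "chembl": 256, "img2seq": 64}[self.variant]

    @property
    def bidirectional(self) -> bool:
        return self.variant == "chembl"

    @property
    def batch_norm(self) -> bool:
        return self.variant == "chembl"

    @property
    def input_kind(self) -> str:
        return "image" if self.variant == "img2seq" else "sequence"


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    lr: list[float] = field(default_factory=list)


class _SeqEncoder(nn.Module):
    def __init__(self, cfg: HeteroencoderConfig, vocab: int, rng,
                 pad_index: int = 0):
        layers = []
        n_in = vocab
        for _ in range(cfg.enc_layers):
            if cfg.bidirectional:
                layers.append(nn.BiLSTM(n_in, cfg.enc_cells, rng))
                n_in = 2 * cfg.enc_cells
            else:
                layers.append(nn.LSTM(n_in, cfg.enc_cells, rng))
                n_in = cfg.enc_cells
        self.layers = layers
        self.bidirectional = cfg.bidirectional
        self.pad_index = pad_index
        # final [H; C] concatenation feeds the code dense
        state_width = 2 * n_in
        self.code_dense = nn.Dense(state_width, cfg.code_dim, activation="relu",
                                   rng=rng)
        self.code_bn = nn.BatchNorm(cfg.code_dim) if cfg.batch_norm else None

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        if self.bidirectional:
            h_final = c_final = None
            current = x
            for layer in self.layers:
                current, h_final, c_final = layer.run(current)
            states = nn.concat([h_final, c_final], axis=1)
        else:
            # unidirectional encoders take [H; C] at each sequence's own
            # end-token position, so trailing padding cannot influence the
            # code (and batches may be trimmed to their longest sequence)
            n, t_steps = x.shape[0], x.shape[1]
            n_pad = x.data[:, :, self.pad_index].sum(axis=1).astype(int)
            last = np.maximum(t_steps - n_pad - 1, 0)
            current = x
            seq = None
            for layer in self.layers:
                seq = layer.run_states(current)
                current = seq[:, :, : layer.n_hidden]
            states = seq[np.arange(n), last, :]  # [h_end, c_end]
        code = self.code_dense(states)
        if self.code_bn is not None:
            code = self.code_bn(code, training)
        return code


class _ImageEncoder(nn.Module):
    """Inception-style convolutional encoder over (N, H, W, 5) images.

    Initial module: towers 1x1->3x3, 1x1->5x5 and a lone 1x1. Standard
    module adds a half-width 1x1->7x7 tower and a maxpool->1x1 tower at
    stride 1; reduction modules drop the 7x7 tower and stride by 2. One
    initial module plus three standard+reduction blocks, flatten, dropout,
    then the ReLU code dense.
    """

    def __init__(self, cfg: HeteroencoderConfig, rng):
        k = cfg.inception_kernels
        self.dropout_rate = cfg.image_dropout

        def tower(c_in, mid, out, kernel, stride=1):
            return [nn.Conv2D(c_in, mid, 1, rng=rng),
                    nn.Conv2D(mid, out, kernel, stride=stride, rng=rng)]

        modules = []
        c_in = 5
        # initial module
        modules.append({
            "towers": [tower(c_in, k, k, 3), tower(c_in, k, k, 5),
                       [nn.Conv2D(c_in, k, 1, rng=rng)]],
            "pool": None, "stride": 1,
        })
        c_in = 3 * k
        for _ in range(3):
            modules.append({
                "towers": [tower(c_in, k, k, 3), tower(c_in, k, k, 5),
                           tower(c_in, k // 2, k // 2, 7)],
                "pool": nn.Conv2D(c_in, k, 1, rng=rng), "stride": 1,
            })
            c_in = 3 * k + k // 2
            modules.append({
                "towers": [tower(c_in, k, k, 3, stride=2),
                           tower(c_in, k, k, 5, stride=2)],
                "pool": nn.Conv2D(c_in, k, 1, rng=rng), "stride": 2,
            })
            c_in = 3 * k
        self.modules_ = modules
        h, w = cfg.image_height, cfg.image_width
        for _ in range(3):
            h, w = -(-h // 2), -(-w // 2)
        self.flat_dim = h * w * c_in
        self.code_dense = nn.Dense(self.flat_dim, cfg.code_dim,
                                   activation="relu", rng=rng)
        self._rng = rng

    def parameters(self):
        params = []
        for mod in self.modules_:
            for tw in mod["towers"]:
                for conv in tw:
                    params.extend(conv.parameters())
            if mod["pool"] is not None:
                params.extend(mod["pool"].parameters())
        params.extend(self.code_dense.parameters())
        return params

    def __call__(self, x: Tensor, training: bool = False) -> Tensor:
        for mod in self.modules_:
            outs = []
            for tw in mod["towers"]:
                y = x
                for conv in tw:
                    y = conv(y)
                outs.append(y)
            if mod["pool"] is not None:
                pooled = nn.maxpool2d(x, size=3, stride=mod["stride"])
                outs.append(mod["pool"](pooled))
            x = nn.concat(outs, axis=3)
        n = x.shape[0]
        flat = x.reshape(n, -1)
        flat = nn.dropout(flat, self.dropout_rate, self._rng, training)
        return self.code_dense(flat)


class _Decoder(nn.Module):
    """Teacher-forced decoder: state-initializer denses + LSTM stack + softmax."""

    def __init__(self, cfg: HeteroencoderConfig, vocab: int, rng):
        self.state_init: list[nn.Dense] = []
        self.state_bn: list[nn.BatchNorm] | None = [] if cfg.batch_norm else None
        for _ in range(cfg.dec_layers):
            for _hc in range(2):  # H and C
                self.state_init.append(
                    nn.Dense(cfg.code_dim, cfg.dec_cells, activation="relu",
                             rng=rng))
                if cfg.batch_norm:
                    self.state_bn.append(nn.BatchNorm(cfg.dec_cells))
        self.lstm_layers = []
        n_in = vocab
        for _ in range(cfg.dec_layers):
            self.lstm_layers.append(nn.LSTM(n_in, cfg.dec_cells, rng))
            n_in = cfg.dec_cells
        self.out_dense = nn.Dense(cfg.dec_cells, vocab, activation=None, rng=rng)

    def parameters(self):
        params = []
        for d in self.state_init:
            params.extend(d.parameters())
        if self.state_bn:
            for bn in self.state_bn:
                params.extend(bn.parameters())
        for l in self.lstm_layers:
            params.extend(l.parameters())
        params.extend(self.out_dense.parameters())
        return params

    def initial_states(self, code: Tensor, training: bool = False):
        """Per-layer (h0, c0) from the code vector; order [H; C] per layer."""
        states = []
        for layer_idx in range(len(self.lstm_layers)):
            pair = []
            for hc in range(2):
                k = 2 * layer_idx + hc
                s = self.state_init[k](code)
                if self.state_bn:
                    s = self.state_bn[k](s, training)
                pair.append(s)
            states.append((pair[0], pair[1]))
        return states

    def teacher_forced_logits(self, code: Tensor, dec_in: Tensor,
                              training: bool = False) -> Tensor:
        states = self.initial_states(code, training)
        current = dec_in
        for layer, (h0, c0) in zip(self.lstm_layers, states):
            current, _, _ = layer.run(current, h0=h0, c0=c0)
        n, t = current.shape[0], current.shape[1]
        flat = current.reshape(n * t, -1)
        logits = self.out_dense(flat)
        return logits.reshape(n, t, -1)


class ModelHandle(nn.Module):
    """Full encoder->code->decoder model plus its data contracts."""

    def __init__(self, config: HeteroencoderConfig, alphabet_in: TokenAlphabet,
                 alphabet_out: TokenAlphabet, maxlen: int):
        if maxlen < 3:
            raise ConfigError("maxlen must fit start + token + end")
        self.config = config
        self.alphabet_in = alphabet_in
        self.alphabet_out = alphabet_out
        self.maxlen = maxlen
        self.trained = False
        rng = np.random.default_rng(config.seed)
        if config.variant == "img2seq":
            self.channel_table = atom_channel_table(list(config.image_elements))
            self.encoder = _ImageEncoder(config, rng)
        else:
            self.channel_table = None
            self.encoder = _SeqEncoder(config, len(alphabet_in), rng,
                                       pad_index=alphabet_in.pad_index)
        self.decoder = _Decoder(config, len(alphabet_out), rng)

    def parameters(self):
        return self.encoder.parameters() + self.decoder.parameters()

    @property
    def n_state_init_layers(self) -> int:
        return len(self.decoder.state_init)

    # -- vectorization helpers ------------------------------------------
    def encode_input(self, smiles_list: list[str], seed: int = 0) -> np.ndarray:
        """Vectorize encoder inputs (one-hot sequences or image tensors)."""
        if self.config.input_kind == "image":
            return np.stack([
                embed_image(s, self.channel_table,
                            height=self.config.image_height,
                            width=self.config.image_width,
                            resolution=self.config.resolution,
                            rotation=0.0, seed=seed)
                for s in smiles_list
            ])
        return np.stack([
            vectorize(s, self.alphabet_in, self.maxlen) for s in smiles_list
        ])

    def target_arrays(self, smiles_list: list[str]):
        """(decoder input one-hot, target indices, non-pad mask)."""
        onehot = np.stack([
            vectorize(s, self.alphabet_out, self.maxlen) for s in smiles_list
        ])
        idx = np.stack([
            token_indices(s, self.alphabet_out, self.maxlen) for s in smiles_list
        ])
        dec_in = onehot[:, :-1, :]
        targets = idx[:, 1:]
        mask = (targets != self.alphabet_out.pad_index).astype(np.float64)
        return dec_in, targets, mask

    # -- forward passes --------------------------------------------------
    def codes(self, enc_in: np.ndarray, training: bool = False) -> Tensor:
        return self.encoder(Tensor(enc_in), training=training)

    def batch_loss(self, enc_in, dec_in, targets, mask, training=True) -> Tensor:
        code = self.codes(enc_in, training=training)
        logits = self.decoder.teacher_forced_logits(code, Tensor(dec_in),
                                                    training=training)
        return nn.softmax_cross_entropy(logits, targets, mask)

    def teacher_forced_probs(self, smiles_in: list[str],
                             smiles_out: list[str]) -> np.ndarray:
        """Per-step output distributions under teacher forcing (inference)."""
        with nn.no_grad():
            enc_in = self.encode_input(smiles_in)
            dec_in, _, _ = self.target_arrays(smiles_out)
            code = self.codes(enc_in)
            logits = self.decoder.teacher_forced_logits(code, Tensor(dec_in))
        return nn.softmax(logits.data, axis=-1)


def build_model(config: HeteroencoderConfig, alphabet_in: TokenAlphabet,
                alphabet_out: TokenAlphabet, maxlen: int) -> ModelHandle:
    """Construct an untrained model for the configured variant."""
    return ModelHandle(config, alphabet_in, alphabet_out, maxlen)


def _dataset_loss(model: ModelHandle, enc_in, dec_in, targets, mask,
                  batch: int = 256) -> float:
    total, weight = 0.0, 0.0
    with nn.no_grad():
        for lo in range(0, enc_in.shape[0], batch):
            sl = slice(lo, lo + batch)
            w = mask[sl].sum()
            loss = model.batch_loss(enc_in[sl], dec_in[sl], targets[sl],
                                    mask[sl], training=False)
            total += float(loss.data) * w
            weight += w
    return total / max(weight, 1.0)


def train(
    model: ModelHandle,
    pairs: list[tuple[str, str]],
    validation_pairs: list[tuple[str, str]] | None = None,
    verbose: bool = False,
) -> tuple[ModelHandle, TrainingHistory]:
    """Train with teacher forcing, Adam, LR-plateau halving and checkpointing.

    The validation pairs drive the learning-rate schedule, early stopping
    and best-weight checkpointing; without them the training loss is
    monitored instead. Deterministic for a fixed config seed.
    """
    cfg = model.config
    rng = np.random.default_rng(cfg.seed + 1)
    inputs = [p[0] for p in pairs]
    enc_in = model.encode_input(inputs)
    dec_in, targets, mask = model.target_arrays([p[1] for p in pairs])
    if validation_pairs:
        v_enc = model.encode_input([p[0] for p in validation_pairs])
        v_dec, v_tgt, v_mask = model.target_arrays(
            [p[1] for p in validation_pairs])

    # length bucketing: unidirectional sequence encoders gather their final
    # states at each sequence's end token, so batches can be trimmed to
    # their longest member without changing any value
    bucketed = cfg.input_kind == "sequence" and not cfg.bidirectional
    if bucketed:
        pad = model.alphabet_in.pad_index
        enc_len = enc_in.shape[1] - enc_in[:, :, pad].sum(axis=1).astype(int)
        dec_len = (mask.sum(axis=1)).astype(int)  # non-pad target positions
        sort_len = np.maximum(enc_len, dec_len + 1)

    params = model.parameters()
    opt = nn.Adam(params, lr=cfg.initial_lr)
    history = TrainingHistory()
    best_val = np.inf
    best_weights = model.get_weights()
    stale = 0
    stop_stale = 0
    n = enc_in.shape[0]

    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        if bucketed:
            # stable sort of a fresh shuffle: random within length classes
            order = order[np.argsort(sort_len[order], kind="stable")]
        batches = [order[lo : lo + cfg.batch_size]
                   for lo in range(0, n, cfg.batch_size)]
        if bucketed:
            batches = [batches[i] for i in rng.permutation(len(batches))]
        epoch_loss, n_batches = 0.0, 0
        for sel in batches:
            if bucketed:
                l_enc = int(enc_len[sel].max())
                l_dec = int(dec_len[sel].max()) + 1
                loss = model.batch_loss(
                    enc_in[sel][:, :l_enc], dec_in[sel][:, : l_dec - 1],
                    targets[sel][:, : l_dec - 1], mask[sel][:, : l_dec - 1],
                    training=True)
            else:
                loss = model.batch_loss(enc_in[sel], dec_in[sel],
                                        targets[sel], mask[sel],
                                        training=True)
            if not np.isfinite(loss.data):
                raise DivergenceError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            loss.backward()
            if cfg.grad_clip:
                norm = np.sqrt(sum(float((p.grad**2).sum())
                                   for p in params if p.grad is not None))
                if norm > cfg.grad_clip:
                    scale = cfg.grad_clip / norm
                    for p in params:
                        if p.grad is not None:
                            p.grad *= scale
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        train_loss = epoch_loss / max(n_batches, 1)
        if validation_pairs:
            val_loss = _dataset_loss(model, v_enc, v_dec, v_tgt, v_mask)
        else:
            val_loss = train_loss
        history.train_loss.append(train_loss)
        history.val_loss.append(val_loss)
        history.lr.append(opt.lr)
        if verbose:
            print(f"epoch {epoch:4d} train {train_loss:.5f} "
                  f"val {val_loss:.5f} lr {opt.lr:.5f}")

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.get_weights()
            stale = 0
            stop_stale = 0
        else:
            stale += 1
            stop_stale += 1
            if stale >= cfg.lr_patience:
                floor = (cfg.min_lr if cfg.min_lr is not None
                         else cfg.initial_lr / 16.0)
                if opt.lr / 2.0 >= floor:  # halve or keep, never clamp
                    opt.lr /= 2.0
                stale = 0
            if (cfg.early_stop_patience is not None
                    and stop_stale >= cfg.early_stop_patience):
                break

    if cfg.restore_best:
        model.set_weights(best_weights)
    model.trained = True
    return model, history


# ---------------------------------------------------------------------------
# split models

class Encoder:
    """Stand-alone encoder with copied weights: molecules -> latent vectors."""

    def __init__(self, model: ModelHandle):
        if not model.trained:
            raise NotTrainedError("split_models requires a trained model")
        self.config = model.config
        self.alphabet_in = model.alphabet_in
        self.maxlen = model.maxlen
        self.channel_table = model.channel_table
        self._net = _clone_encoder(model)
        self._vectorize = model.encode_input

    def transform(self, enc_in: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            return self._net(Tensor(enc_in)).data

    def encode_smiles(self, smiles_list: list[str], seed: int = 0) -> np.ndarray:
        if not smiles_list:
            return np.zeros((0, self.config.code_dim))
        return self.transform(self._vectorize(smiles_list, seed=seed))


class StateInitializer:
    """Code vector -> initial (H, C) states for each decoder LSTM layer."""

    def __init__(self, model: ModelHandle):
        if not model.trained:
            raise NotTrainedError("split_models requires a trained model")
        self._decoder = _clone_decoder(model)

    def __call__(self, code: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        code = np.atleast_2d(np.asarray(code, dtype=np.float64))
        with nn.no_grad():
            states = self._decoder.initial_states(Tensor(code))
            return [(h.data, c.data) for h, c in states]


class StatefulStepDecoder:
    """Single-step decoder holding LSTM states between calls."""

    def __init__(self, model: ModelHandle):
        if not model.trained:
            raise NotTrainedError("split_models requires a trained model")
        self.alphabet = model.alphabet_out
        self._decoder = _clone_decoder(model)
        self._states: list[list[Tensor]] | None = None

    def init_states(self, states: list[tuple[np.ndarray, np.ndarray]]) -> None:
        self._states = [[Tensor(np.atleast_2d(h)), Tensor(np.atleast_2d(c))]
                        for h, c in states]

    def reset(self) -> None:
        self._states = None

    def step(self, token_index: int) -> np.ndarray:
        """Feed one token, return the next-token probability vector."""
        if self._states is None:
            raise StateError("step decoder used before init_states()")
        x = np.zeros((1, len(self.alphabet)))
        x[0, token_index] = 1.0
        with nn.no_grad():
            current = Tensor(x)
            for layer, st in zip(self._decoder.lstm_layers, self._states):
                h, c = layer.step(current, st[0], st[1])
                st[0], st[1] = h, c
                current = h
            logits = self._decoder.out_dense(current)
        return nn.softmax(logits.data, axis=-1)[0]


def _clone_encoder(model: ModelHandle):
    fresh = ModelHandle(model.config, model.alphabet_in, model.alphabet_out,
                        model.maxlen)
    fresh.set_weights(model.get_weights())
    _copy_batchnorm_stats(model, fresh)
    return fresh.encoder


def _clone_decoder(model: ModelHandle) -> _Decoder:
    fresh = ModelHandle(model.config, model.alphabet_in, model.alphabet_out,
                        model.maxlen)
    fresh.set_weights(model.get_weights())
    _copy_batchnorm_stats(model, fresh)
    return fresh.decoder


def _copy_batchnorm_stats(src: ModelHandle, dst: ModelHandle) -> None:
    for a, b in zip(_batchnorms(src), _batchnorms(dst)):
        b.running_mean = a.running_mean.copy()
        b.running_var = a.running_var.copy()


def _batchnorms(model: ModelHandle) -> list[nn.BatchNorm]:
    bns = []
    enc = model.encoder
    if isinstance(enc, _SeqEncoder) and enc.code_bn is not None:
        bns.append(enc.code_bn)
    if model.decoder.state_bn:
        bns.extend(model.decoder.state_bn)
    return bns


def split_models(trained: ModelHandle):
    """Extract (Encoder, StateInitializer, StatefulStepDecoder) with copied
    weights, mirroring the deployment decomposition of the full model."""
    return (Encoder(trained), StateInitializer(trained),
            StatefulStepDecoder(trained))


# ---------------------------------------------------------------------------
# encoding & decoding

def encode(encoder: Encoder, molecules: list[str],
           representation: str = "canonical", seed: int = 0) -> np.ndarray:
    """Latent vectors for molecules under a chosen input representation.

    ``canonical`` encodes the canonical SMILES, ``enumerated`` one seeded
    random enumeration per molecule, ``image`` the 2D embedding (image
    encoders only).
    """
    if representation not in ("canonical", "enumerated", "image"):
        raise ConfigError(f"unknown representation {representation!r}")
    needs_image = encoder.config.input_kind == "image"
    if (representation == "image") != needs_image:
        raise ConfigError(
            f"representation {representation!r} does not match a "
            f"{encoder.config.variant} encoder")
    if not molecules:
        return np.zeros((0, encoder.config.code_dim))
    if representation == "enumerated":
        rng = np.random.default_rng(seed)
        mols = [enumerate_smiles(m, 1, seed=int(rng.integers(2**31 - 1)))[0]
                for m in molecules]
    else:
        mols = [canonicalize(m) for m in molecules]
    return encoder.encode_smiles(mols, seed=seed)


def encode_strings(encoder: Encoder, smiles: list[str]) -> np.ndarray:
    """Latent vectors for SMILES strings used verbatim (no canonicalization)."""
    return encoder.encode_smiles(smiles)


def decode_greedy(latent: np.ndarray, step_decoder: StatefulStepDecoder,
                  state_init: StateInitializer, max_steps: int = 100
                  ) -> tuple[str, list[np.ndarray]]:
    """Most-probable-character decoding from a latent vector.

    Returns the raw decoded string (which may or may not be a valid
    SMILES — that is a data outcome) and the per-step probability vectors.
    """
    alphabet = step_decoder.alphabet
    step_decoder.init_states(state_init(latent))
    token = alphabet.start_index
    chars: list[str] = []
    prob_records: list[np.ndarray] = []
    for _ in range(max_steps):
        probs = step_decoder.step(token)
        prob_records.append(probs)
        token = int(probs.argmax())
        if token == alphabet.end_index or token == alphabet.pad_index:
            break
        chars.append(alphabet.tokens[token])
    step_decoder.reset()
    return "".join(chars), prob_records


def decode_multinomial(latent: np.ndarray, step_decoder: StatefulStepDecoder,
                       state_init: StateInitializer, temperature: float = 1.0,
                       n: int = 1, seed: int = 0, max_steps: int = 100
                       ) -> tuple[list[str], list[list[np.ndarray]]]:
    """Multinomial sampling of the decoder at a given temperature.

    Each step's distribution is sharpened as p_i^(1/t), renormalized, and
    sampled. Temperatures at or below 1e-6 reduce to greedy decoding.
    Deterministic for a fixed seed.
    """
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if n < 1:
        raise ValueError("n must be >= 1")
    alphabet = step_decoder.alphabet
    rng = np.random.default_rng(seed)
    samples: list[str] = []
    records: list[list[np.ndarray]] = []
    greedy_limit = temperature <= 1e-6
    for _ in range(n):
        step_decoder.init_states(state_init(latent))
        token = alphabet.start_index
        chars: list[str] = []
        rec: list[np.ndarray] = []
        for _step in range(max_steps):
            probs = step_decoder.step(token)
            rec.append(probs)
            if greedy_limit:
                token = int(probs.argmax())
            else:
                w = np.power(np.maximum(probs, 1e-300), 1.0 / temperature)
                w /= w.sum()
                token = int(rng.choice(len(w), p=w))
            if token == alphabet.end_index or token == alphabet.pad_index:
                break
            chars.append(alphabet.tokens[token])
        samples.append("".join(chars))
        records.append(rec)
    step_decoder.reset()
    return samples, records


# ---------------------------------------------------------------------------
# persistence

def save_model(model: ModelHandle, directory: str | Path) -> None:
    """Save weights (npz) plus a JSON sidecar describing the contracts."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    weights = model.get_weights()
    np.savez(directory / "weights.npz",
             **{f"w{i}": w for i, w in enumerate(weights)})
    bns = _batchnorms(model)
    if bns:
        np.savez(directory / "batchnorm.npz",
                 **{f"m{i}": bn.running_mean for i, bn in enumerate(bns)},
                 **{f"v{i}": bn.running_var for i, bn in enumerate(bns)})
    sidecar = {
        "config": asdict(model.config),
        "alphabet_in": list(model.alphabet_in.tokens),
        "alphabet_out": list(model.alphabet_out.tokens),
        "maxlen": model.maxlen,
        "trained": model.trained,
        "n_weights": len(weights),
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=1))


def load_model(directory: str | Path) -> ModelHandle:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    cfg_doc = dict(sidecar["config"])
    cfg_doc["image_elements"] = tuple(cfg_doc["image_elements"])
    cfg = HeteroencoderConfig(**cfg_doc)
    alpha_in = TokenAlphabet(tokens=tuple(sidecar["alphabet_in"]))
    alpha_out = TokenAlphabet(tokens=tuple(sidecar["alphabet_out"]))
    model = ModelHandle(cfg, alpha_in, alpha_out, sidecar["maxlen"])
    data = np.load(directory / "weights.npz")
    model.set_weights([data[f"w{i}"] for i in range(sidecar["n_weights"])])
    bn_path = directory / "batchnorm.npz"
    if bn_path.exists():
        bn_data = np.load(bn_path)
        for i, bn in enumerate(_batchnorms(model)):
            bn.running_mean = bn_data[f"m{i}"]
            bn.running_var = bn_data[f"v{i}"]
    model.trained = bool(sidecar["trained"])
    return model
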