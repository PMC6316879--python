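"""End-to-end seeded experiment workflows with config files and logging.

A single flat :class:`ExperimentConfig` fully determines a run. The pilot
workflow trains one auto-/heteroencoder on the fixture set and emits the
model's report card: test loss, malformed/wrong-molecule percentages under
greedy decoding, the two latent-similarity correlations, multinomial
sampling statistics, the reconstruction-error partition and the
enumeration-challenge spreads. The QSAR workflow compares fingerprint
features against latent vectors from one or more trained encoders on a
synthetic structure-derived property.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import datasets, evaluation, latent, qsar
from . import model as model_mod
from .errors import ConfigError
from .representations import (
    canonicalize,
    enumeration_closed_alphabet,
    tokenize,
)

logger = logging.getLogger("molhetero")

CONFIG_VERSION = 1


def _log(event: str, **fields) -> None:
    logger.info(json.dumps({"event": event, **fields}, sort_keys=True))


@dataclass
class ExperimentConfig:
    """Flat, versioned description of one experiment."""

    version: int = CONFIG_VERSION
    seed: int = 0
    output_dir: str = "molhetero_run"
    # data: either a SMILES file or the synthetic fixture set
    input_file: str | None = None
    max_heavy_atoms: int = 4
    elements: tuple[str, ...] = ("C", "N", "O")
    allow_rings: bool = True
    n_max: int | None = None
    split_ratio: float = 0.9
    # pairing and model
    pairing_mode: str = "can2can"
    n_enum: int = 10
    variant: str = "seq1"
    code_dim: int | None = None
    encoder_cells: int | None = None
    decoder_cells: int | None = None
    epochs: int = 100
    batch_size: int = 64
    initial_lr: float = 0.005
    lr_patience: int = 5
    early_stop_patience: int | None = None
    restore_best: bool = True
    # evaluation options
    n_samples: int = 1000
    temperature: float = 1.0
    challenge_n_enum: int = 10
    challenge_molecules: int = 3
    # qsar options
    qsar_feature_types: tuple[str, ...] = ("ecfp4",)
    qsar_budget: int = 8
    qsar_noise_sd: float = 0.1
    qsar_epochs: int = 60
    qsar_folds: int = 10
    qsar_train_missing: bool = True

    def to_file(self, path: str | Path) -> None:
        doc = asdict(self)
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_file(cls, path: str | Path) -> "ExperimentConfig":
        doc = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "ExperimentConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if doc.get("version", CONFIG_VERSION) != CONFIG_VERSION:
            raise ConfigError(f"unsupported config version {doc.get('version')}")
        doc = dict(doc)
        for key in ("elements", "qsar_feature_types"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        return cls(**doc)

    def config_hash(self) -> str:
        doc = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(doc.encode()).hexdigest()[:16]


def load_molecules(config: ExperimentConfig) -> list[str]:
    """Fixture molecules or canonicalized molecules from the input file."""
    if config.input_file:
        from .representations import read_smiles_file

        return [canonicalize(s) for s in read_smiles_file(config.input_file)]
    spec = datasets.FixtureSpec(
        max_heavy_atoms=config.max_heavy_atoms,
        elements=config.elements,
        allow_rings=config.allow_rings,
        n_max=config.n_max,
        seed=config.seed,
    )
    return datasets.generate_fixture_molecules(spec)


def corpus_maxlen(molecules: list[str], n_enum_probe: int = 20,
                  enumerated: bool = False, seed: int = 0) -> int:
    """Token budget: longest corpus string plus start/end and headroom.

    Enumerated serializations can be longer than canonical ones (ring
    openings move), so a probe enumeration widens the budget when needed.
    """
    longest = max(len(tokenize(s)) for s in molecules)
    if enumerated:
        from .representations import enumerate_smiles

        rng = np.random.default_rng(seed)
        probe = [molecules[i] for i in
                 rng.choice(len(molecules), min(50, len(molecules)),
                            replace=False)]
        for smi in probe:
            for e in enumerate_smiles(smi, n_enum_probe,
                                      seed=int(rng.integers(2**31 - 1))):
                longest = max(longest, len(tokenize(e)))
        longest += 2  # headroom for unseen enumerations
    return longest + 2  # start + end


def build_and_train(
    config: ExperimentConfig,
    train_molecules: list[str],
    test_molecules: list[str],
) -> tuple[model_mod.ModelHandle, model_mod.TrainingHistory]:
    """Make pairs, build the configured model and train it.

    Following the small-dataset protocol, the held-out test split serves
    as the validation set that drives the learning-rate schedule.
    """
    pairing = datasets.PairingMode(mode=config.pairing_mode,
                                   n_enum=config.n_enum)
    pairs = datasets.make_training_pairs(train_molecules, pairing,
                                         seed=config.seed)
    val_pairs = datasets.make_training_pairs(test_molecules, pairing,
                                             seed=config.seed + 1)
    # enumeration-closed contracts even for canonical training: trained
    # encoders are later challenged with enumerated SMILES
    corpus = train_molecules + test_molecules
    alphabet = enumeration_closed_alphabet(corpus)
    maxlen = corpus_maxlen(corpus, enumerated=True, seed=config.seed)
    mcfg = model_mod.HeteroencoderConfig(
        variant=config.variant,
        code_dim=config.code_dim,
        batch_size=config.batch_size,
        epochs=config.epochs,
        initial_lr=config.initial_lr,
        lr_patience=config.lr_patience,
        early_stop_patience=config.early_stop_patience,
        restore_best=config.restore_best,
        seed=config.seed,
        encoder_cells=config.encoder_cells,
        decoder_cells=config.decoder_cells,
    )
    handle = model_mod.build_model(mcfg, alphabet, alphabet, maxlen)
    _log("training_start", variant=config.variant, mode=config.pairing_mode,
         n_pairs=len(pairs), maxlen=maxlen, vocab=len(alphabet))
    trained, history = model_mod.train(handle, pairs, val_pairs)
    _log("training_done", best_val=min(history.val_loss),
         epochs_run=len(history.train_loss))
    return trained, history


def greedy_reconstruction(trained: model_mod.ModelHandle,
                          molecules: list[str]):
    """Greedy-decode every molecule from its latent; returns decodes and
    per-molecule reconstruction reports."""
    encoder, state_init, step_dec = model_mod.split_models(trained)
    latents = encoder.encode_smiles(molecules)
    decoded, reports = [], []
    for smi, vec in zip(molecules, latents):
        out, _ = model_mod.decode_greedy(vec, step_dec, state_init,
                                         max_steps=trained.maxlen)
        decoded.append(out)
        reports.append(evaluation.reconstruction_report(smi, out))
    return decoded, reports


def run_pilot(config: ExperimentConfig) -> dict:
    """Train one model and compute its full report bundle (files + dict)."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    molecules = load_molecules(config)
    train_set, test_set = datasets.split_train_test(
        molecules, config.split_ratio, seed=config.seed)
    trained, history = build_and_train(config, train_set, test_set)

    decoded, reports = greedy_reconstruction(trained, test_set)
    n_valid = sum(1 for r in reports if r.valid)
    pct_malformed = 100.0 * (len(reports) - n_valid) / len(reports)
    wrong = sum(1 for r in reports if r.valid and not r.same_molecule)
    pct_wrong = 100.0 * wrong / max(n_valid, 1)
    partition = evaluation.aggregate_errors(reports)

    encoder, state_init, step_dec = model_mod.split_models(trained)
    reference = test_set[int(rng.integers(len(test_set)))]
    # a very small held-out split gives degenerate similarity spreads; fall
    # back to the training molecules as the comparison set in that case
    comparison = test_set if len(test_set) >= 20 else train_set
    r2_fp, r2_seq = latent.similarity_correlations(reference, comparison,
                                                   encoder)

    ref_latent = encoder.encode_smiles([reference])[0]
    samples, _ = model_mod.decode_multinomial(
        ref_latent, step_dec, state_init, temperature=config.temperature,
        n=config.n_samples, seed=config.seed + 42, max_steps=trained.maxlen)
    stats = evaluation.sampling_statistics(samples, reference)

    challenge_mols = [test_set[i] for i in
                      rng.choice(len(test_set),
                                 min(config.challenge_molecules, len(test_set)),
                                 replace=False)]
    challenge = latent.enumeration_challenge(
        encoder, challenge_mols, n_enum=config.challenge_n_enum,
        background=test_set, seed=config.seed)

    report = {
        "loss": float(min(history.val_loss)),
        "pct_malformed": pct_malformed,
        "pct_wrong_molecule": pct_wrong,
        "r2_fingerprint": r2_fp,
        "r2_sequence": r2_seq,
        "sampling": asdict(stats),
        "error_partition": partition,
        "challenge_spreads": challenge.spreads,
        "mean_challenge_spread": float(np.mean(list(challenge.spreads.values()))),
        "reference_molecule": canonicalize(reference),
        "n_train": len(train_set),
        "n_test": len(test_set),
    }

    _write_pilot_files(out_dir, config, report, test_set, decoded, reports,
                       challenge)
    _log("pilot_done", **{k: v for k, v in report.items()
                          if isinstance(v, (int, float, str))})
    return report


def _write_pilot_files(out_dir, config, report, test_set, decoded, reports,
                       challenge) -> None:
    (out_dir / "report.json").write_text(json.dumps(report, indent=1,
                                                    sort_keys=True))
    with open(out_dir / "summary.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["loss", "pct_malformed", "pct_wrong_molecule",
                         "r2_fingerprint", "r2_sequence"])
        writer.writerow([f"{report['loss']:.6f}",
                         f"{report['pct_malformed']:.2f}",
                         f"{report['pct_wrong_molecule']:.2f}",
                         f"{report['r2_fingerprint']:.4f}",
                         f"{report['r2_sequence']:.4f}"])
    evaluation.write_reports_csv(out_dir / "reconstruction.csv", test_set,
                                 decoded, reports)
    latent.write_challenge_csv(out_dir / "challenge.csv", challenge)
    latent.write_spread_json(out_dir / "challenge_spreads.json", challenge)
    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "files": sorted(p.name for p in out_dir.iterdir() if p.is_file()
                        and p.name != "manifest.json"),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    config.to_file(out_dir / "config.yaml")


def run_qsar_study(config: ExperimentConfig,
                   encoders: dict[str, model_mod.Encoder] | None = None
                   ) -> dict:
    """Fingerprints vs latent vectors on the synthetic property task.

    ``qsar_feature_types`` lists "ecfp4" and/or pairing modes (can2can,
    enum2can, ...). Encoders for the pairing modes are taken from
    ``encoders`` or trained from the config. Hyperparameters are searched
    on the fingerprint features and reused unchanged for latent features.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    molecules = load_molecules(config)
    train_set, test_set = datasets.split_train_test(
        molecules, config.split_ratio, seed=config.seed)
    y_train = datasets.synthetic_property(train_set, config.qsar_noise_sd,
                                          seed=config.seed)
    y_test = datasets.synthetic_property(test_set, config.qsar_noise_sd,
                                         seed=config.seed + 1)

    encoders = dict(encoders or {})
    feature_sets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ftype in config.qsar_feature_types:
        if ftype == "ecfp4":
            feature_sets[ftype] = (qsar.ecfp4_features(train_set),
                                   qsar.ecfp4_features(test_set))
            continue
        if ftype not in encoders:
            if not config.qsar_train_missing:
                raise ConfigError(
                    f"no encoder supplied for feature type {ftype!r}")
            sub = dataclasses.replace(config, pairing_mode=ftype)
            trained, _ = build_and_train(sub, train_set, test_set)
            encoders[ftype], _, _ = model_mod.split_models(trained)
        enc = encoders[ftype]
        feature_sets[ftype] = (qsar.latent_features(enc, train_set),
                               qsar.latent_features(enc, test_set))

    if "ecfp4" in feature_sets:
        X_search = feature_sets["ecfp4"][0]
    else:
        X_search = next(iter(feature_sets.values()))[0]
    best_cfg, best_cv = qsar.hyperparameter_search(
        qsar.HyperparameterSpace(), X_search, y_train,
        budget=config.qsar_budget, seed=config.seed,
        epochs=config.qsar_epochs)
    _log("qsar_search_done", cv_mse=best_cv)

    metrics = {}
    for ftype, (X_tr, X_te) in feature_sets.items():
        m = qsar.fit_ensemble_evaluate(best_cfg, X_tr, y_train, X_te, y_test,
                                       seed=config.seed,
                                       n_folds=config.qsar_folds,
                                       epochs=config.qsar_epochs)
        metrics[ftype] = {"r2": m.r2, "rmse": m.rmse}
        _log("qsar_evaluated", features=ftype, r2=m.r2, rmse=m.rmse)

    result = {
        "hyperparameters": qsar.config_to_dict(best_cfg),
        "cv_mse": best_cv,
        "metrics": metrics,
        "n_train": len(train_set),
        "n_test": len(test_set),
    }
    (out_dir / "qsar_report.json").write_text(
        json.dumps(result, indent=1, sort_keys=True))
    with open(out_dir / "qsar_metrics.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["features", "r2", "rmse"])
        for ftype, m in metrics.items():
            writer.writerow([ftype, f"{m['r2']:.4f}", f"{m['rmse']:.4f}"])
    manifest = {"config_hash": config.config_hash(), "seed": config.seed,
                "files": ["qsar_report.json", "qsar_metrics.csv"]}
    (out_dir / "qsar_manifest.json").write_text(json.dumps(manifest, indent=1))
    return result
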