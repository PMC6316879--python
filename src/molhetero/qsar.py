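"""QSAR on ECFP4 fingerprints vs encoder latent vectors.

Protocol: a feed-forward network's hyperparameters are searched with
3-fold cross-validation on the training set using the ECFP4 features; the
winning configuration is then reused unchanged for the latent-vector
features (no re-search). Final test-set performance comes from an ensemble
of the 10 fold models of a 10-fold cross-validation fit, reported as the
squared Pearson correlation (R^2) and RMSE of the averaged predictions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, asdict

import numpy as np
from rdkit import DataStructs
from rdkit.Chem import rdFingerprintGenerator
from scipy import stats

from . import nn
from .errors import DegenerateDataError, SearchFailedError
from .model import Encoder, encode
from .representations import mol_from_smiles


@dataclass(frozen=True)
class QsarConfig:
    """One concrete feed-forward configuration drawn from the search space."""

    input_dropout: float = 0.0
    units_per_layer: int = 64
    l2: float = 1e-4
    maxnorm: float = 3.0
    initializer: str = "glorot_uniform"
    batch_norm: bool = False
    activation: str = "relu"
    dropout: float = 0.0
    hidden_layers: int = 2
    learning_rate: float = 1e-3
    optimizer: str = "adam"


@dataclass(frozen=True)
class HyperparameterSpace:
    """Bounded search space for the QSAR networks.

    Continuous parameters spanning two or more orders of magnitude (L2,
    learning rate) are sampled log-uniformly, the rest uniformly.
    """

    input_dropout: tuple[float, float] = (0.0, 0.95)
    units_per_layer: tuple[int, int] = (2, 1024)
    l2: tuple[float, float] = (1e-6, 0.1)
    maxnorm: tuple[float, float] = (0.5, 6.0)
    initializers: tuple[str, ...] = nn.INITIALIZERS
    batch_norm: tuple[bool, ...] = (True, False)
    activations: tuple[str, ...] = ("relu", "selu")
    dropout: tuple[float, float] = (0.0, 0.95)
    hidden_layers: tuple[int, int] = (1, 6)
    learning_rate: tuple[float, float] = (1e-5, 0.1)
    optimizers: tuple[str, ...] = ("adam", "nadam", "rmsprop", "sgd")

    def sample(self, rng: np.random.Generator) -> QsarConfig:
        def log_uniform(lo, hi):
            return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

        return QsarConfig(
            input_dropout=float(rng.uniform(*self.input_dropout)),
            units_per_layer=int(rng.integers(self.units_per_layer[0],
                                             self.units_per_layer[1] + 1)),
            l2=log_uniform(*self.l2),
            maxnorm=float(rng.uniform(*self.maxnorm)),
            initializer=str(rng.choice(self.initializers)),
            batch_norm=bool(rng.choice(np.array(self.batch_norm))),
            activation=str(rng.choice(self.activations)),
            dropout=float(rng.uniform(*self.dropout)),
            hidden_layers=int(rng.integers(self.hidden_layers[0],
                                           self.hidden_layers[1] + 1)),
            learning_rate=log_uniform(*self.learning_rate),
            optimizer=str(rng.choice(self.optimizers)),
        )

    def contains(self, cfg: QsarConfig) -> bool:
        return (
            self.input_dropout[0] <= cfg.input_dropout <= self.input_dropout[1]
            and self.units_per_layer[0] <= cfg.units_per_layer
            <= self.units_per_layer[1]
            and self.l2[0] <= cfg.l2 <= self.l2[1]
            and self.maxnorm[0] <= cfg.maxnorm <= self.maxnorm[1]
            and cfg.initializer in self.initializers
            and cfg.batch_norm in self.batch_norm
            and cfg.activation in self.activations
            and self.dropout[0] <= cfg.dropout <= self.dropout[1]
            and self.hidden_layers[0] <= cfg.hidden_layers
            <= self.hidden_layers[1]
            and self.learning_rate[0] <= cfg.learning_rate
            <= self.learning_rate[1]
            and cfg.optimizer in self.optimizers
        )


@dataclass(frozen=True)
class QsarMetrics:
    r2: float
    rmse: float


_ECFP4 = rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=1024)


def ecfp4_features(molecules: list[str]) -> np.ndarray:
    """N x 1024 binary ECFP4 matrix (Morgan radius 2 hashed to 1024 bits)."""
    rows = []
    for smi in molecules:
        fp = _ECFP4.GetFingerprint(mol_from_smiles(smi))
        arr = np.zeros(1024, dtype=np.float64)
        DataStructs.ConvertToNumpyArray(fp, arr)
        rows.append(arr)
    return np.stack(rows)


def latent_features(encoder: Encoder, molecules: list[str]) -> np.ndarray:
    """N x code_dim latent-vector feature matrix from a trained encoder."""
    return encode(encoder, molecules, representation="canonical")


class _QsarNet(nn.Module):
    def __init__(self, n_in: int, cfg: QsarConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.hidden: list[nn.Dense] = []
        self.bns: list[nn.BatchNorm] = []
        width = n_in
        for _ in range(cfg.hidden_layers):
            self.hidden.append(nn.Dense(width, cfg.units_per_layer,
                                        activation=cfg.activation, rng=rng,
                                        initializer=cfg.initializer))
            if cfg.batch_norm:
                self.bns.append(nn.BatchNorm(cfg.units_per_layer))
            width = cfg.units_per_layer
        self.out = nn.Dense(width, 1, activation=None, rng=rng,
                            initializer=cfg.initializer)
        self._rng = rng

    def parameters(self):
        params = []
        for d in self.hidden:
            params.extend(d.parameters())
        for bn in self.bns:
            params.extend(bn.parameters())
        params.extend(self.out.parameters())
        return params

    def forward(self, x: nn.Tensor, training: bool) -> nn.Tensor:
        x = nn.dropout(x, self.cfg.input_dropout, self._rng, training)
        for i, dense in enumerate(self.hidden):
            x = dense(x)
            if self.cfg.batch_norm:
                x = self.bns[i](x, training)
            x = nn.dropout(x, self.cfg.dropout, self._rng, training)
        return self.out(x)

    def l2_penalty(self) -> nn.Tensor:
        total = nn.Tensor(0.0)
        for dense in self.hidden + [self.out]:
            total = total + (dense.weight**2.0).sum()
        return total * self.cfg.l2

    def apply_maxnorm(self) -> None:
        for dense in self.hidden + [self.out]:
            w = dense.weight.data
            norms = np.sqrt((w**2).sum(axis=0, keepdims=True))
            factor = np.minimum(1.0, self.cfg.maxnorm / np.maximum(norms, 1e-12))
            dense.weight.data = w * factor


def _fit_net(X: np.ndarray, y: np.ndarray, cfg: QsarConfig, seed: int,
             epochs: int, batch_size: int = 32):
    """Train one network on z-scored targets; returns a predict function."""
    rng = np.random.default_rng(seed)
    y_mean, y_sd = float(y.mean()), float(y.std())
    y_sd = y_sd if y_sd > 0 else 1.0
    yz = (y - y_mean) / y_sd
    net = _QsarNet(X.shape[1], cfg, rng)
    opt = nn.make_optimizer(cfg.optimizer, net.parameters(), cfg.learning_rate)
    n = X.shape[0]
    for _epoch in range(epochs):
        order = rng.permutation(n)
        for lo in range(0, n, batch_size):
            sel = order[lo : lo + batch_size]
            pred = net.forward(nn.Tensor(X[sel]), training=True)
            err = pred.reshape(-1) - nn.Tensor(yz[sel])
            loss = (err**2.0).mean() + net.l2_penalty()
            if not np.isfinite(loss.data):
                return None
            opt.zero_grad()
            loss.backward()
            opt.step()
            net.apply_maxnorm()

    def predict(X_new: np.ndarray) -> np.ndarray:
        with nn.no_grad():
            out = net.forward(nn.Tensor(X_new), training=False)
        return out.data.reshape(-1) * y_sd + y_mean

    return predict


def _kfold_indices(n: int, k: int, rng: np.random.Generator):
    order = rng.permutation(n)
    return np.array_split(order, k)


def _fold_seed(seed: int, val_idx: np.ndarray) -> int:
    """Per-fold seed derived from the fold's membership, not its position,
    so the ensemble is invariant to fold order."""
    digest = zlib.crc32(np.sort(val_idx).astype(np.int64).tobytes())
    return int((seed + digest) % (2**31 - 1))


def cross_val_mse(cfg: QsarConfig, X: np.ndarray, y: np.ndarray, folds: int,
                  seed: int, epochs: int = 60) -> float:
    """Mean squared error over k-fold cross-validation (the search loss)."""
    rng = np.random.default_rng(seed)
    parts = _kfold_indices(len(y), folds, rng)
    errs = []
    for i, val_idx in enumerate(parts):
        train_idx = np.concatenate([p for j, p in enumerate(parts) if j != i])
        predict = _fit_net(X[train_idx], y[train_idx], cfg,
                           _fold_seed(seed, val_idx), epochs)
        if predict is None:
            return float("nan")
        pred = predict(X[val_idx])
        errs.append(np.mean((pred - y[val_idx]) ** 2))
    return float(np.mean(errs))


def hyperparameter_search(
    space: HyperparameterSpace,
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 3,
    budget: int = 20,
    seed: int = 0,
    optimizer: str = "random",
    epochs: int = 60,
) -> tuple[QsarConfig, float]:
    """Search the space for the lowest CV-MSE configuration.

    ``optimizer`` is ``"random"`` (seeded random search) or a callable
    plugin with signature (space, objective, budget, rng) -> QsarConfig —
    the hook where a TPE implementation can be substituted.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if len(y) < folds:
        raise ValueError("need at least `folds` samples")
    rng = np.random.default_rng(seed)

    def objective(cfg: QsarConfig) -> float:
        if not space.contains(cfg):
            raise ValueError(f"candidate outside the search space: {cfg}")
        return cross_val_mse(cfg, X, y, folds, seed=seed, epochs=epochs)

    if callable(optimizer):
        best_cfg = optimizer(space, objective, budget, rng)
        return best_cfg, objective(best_cfg)
    if optimizer != "random":
        raise ValueError("optimizer must be 'random' or a callable plugin")
    best_cfg, best_loss = None, np.inf
    for _ in range(budget):
        cfg = space.sample(rng)
        loss = objective(cfg)
        if np.isfinite(loss) and loss < best_loss:
            best_cfg, best_loss = cfg, loss
    if best_cfg is None:
        raise SearchFailedError("all candidates produced NaN losses")
    return best_cfg, float(best_loss)


def fit_ensemble_evaluate(
    config: QsarConfig,
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    seed: int = 0,
    n_folds: int = 10,
    epochs: int = 100,
) -> QsarMetrics:
    """Test-set metrics from an ensemble of the 10-fold CV fold models.

    Each fold model is trained on its k-1 folds; the test prediction is
    the mean over fold models (so invariant to fold order). R^2 is the
    squared Pearson correlation between predictions and targets.
    """
    if np.ptp(y_test) == 0 or np.ptp(y_train) == 0:
        raise DegenerateDataError("targets have zero variance")
    rng = np.random.default_rng(seed)
    parts = _kfold_indices(len(y_train), n_folds, rng)
    preds = []
    for val_idx in parts:
        train_idx = np.concatenate(
            [p for p in parts if not np.array_equal(p, val_idx)])
        predict = _fit_net(X_train[train_idx], y_train[train_idx], config,
                           _fold_seed(seed, val_idx), epochs)
        if predict is None:
            raise DegenerateDataError("fold model diverged")
        preds.append(predict(X_test))
    ensemble = np.mean(preds, axis=0)
    r2 = float(stats.pearsonr(ensemble, y_test).statistic ** 2)
    rmse = float(np.sqrt(np.mean((ensemble - y_test) ** 2)))
    return QsarMetrics(r2=r2, rmse=rmse)


def normalized_average_rmse(rmses: dict[str, float], baseline: str = "ecfp4"
                            ) -> dict[str, float]:
    """RMSEs normalized by the fingerprint-baseline RMSE (for averaging
    across endpoints with different units)."""
    base = rmses[baseline]
    return {k: v / base for k, v in rmses.items()}


def config_to_dict(cfg: QsarConfig) -> dict:
    return asdict(cfg)
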