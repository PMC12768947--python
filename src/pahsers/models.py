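"""1D CNN classifier and regressor for multiplexed spectra.

The classifier maps a unit-max spectrum to 5 independent presence
probabilities (one sigmoid per target, multilabel); the regressor maps it
to the 6 continuous labels (5 fractional contributions plus the
normalization factor z). Both share the same backbone: 3 convolutional
blocks and 1 dense layer, differing only in the output head.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np

from .mixtures import SimDataset
from .nn import (
    Adam,
    Conv1D,
    Dense,
    Dropout,
    Flatten,
    MaxPool1D,
    Network,
    ReLU,
    bce_with_logits,
    mse_loss,
    sigmoid,
)
from .spectra import SpectrumSet

__all__ = [
    "ArchitectureConfig",
    "TrainingConfig",
    "TrainedModel",
    "ModelError",
    "build_model",
    "train",
    "predict_scores",
    "search_architecture",
    "DEFAULT_SEARCH_SPACE",
]

N_TARGETS = 5


class ModelError(RuntimeError):
    """Configuration or state errors in model building/training."""


@dataclass(frozen=True)
class ArchitectureConfig:
    """Backbone shape: (filters, kernel, pool) per conv block + one dense layer.

    Filter counts are sized for single-CPU training at the default dataset
    sizes; the search op exists to re-tune them.
    """

    conv_blocks: tuple[tuple[int, int, int], ...] = ((8, 9, 2), (16, 9, 2), (32, 9, 2))
    dense_units: int = 64
    dropout: float = 0.2
    head: str = "classifier"

    def __post_init__(self) -> None:
        if self.head not in ("classifier", "regressor"):
            raise ModelError(f"unknown head {self.head!r}")
        if not 0 <= self.dropout < 1:
            raise ModelError("dropout must be in [0, 1)")
        for f, k, p in self.conv_blocks:
            if k % 2 == 0:
                raise ModelError(f"kernel width must be odd, got {k}")
            if f < 1 or p < 1:
                raise ModelError("filters and pool width must be positive")

    @property
    def n_outputs(self) -> int:
        return N_TARGETS if self.head == "classifier" else N_TARGETS + 1

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, text: str) -> "ArchitectureConfig":
        d = json.loads(text)
        d["conv_blocks"] = tuple(tuple(b) for b in d["conv_blocks"])
        return cls(**d)


@dataclass(frozen=True)
class TrainingConfig:
    max_epochs: int = 40
    batch_size: int = 64
    learning_rate: float = 1e-3
    patience: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.max_epochs, self.batch_size, self.patience) < 1 or self.learning_rate <= 0:
            raise ModelError("training parameters must be positive")
        if self.patience >= self.max_epochs:
            raise ModelError("patience must be smaller than max_epochs")


@dataclass
class TrainedModel:
    architecture: ArchitectureConfig
    network: Network
    input_length: int
    seed: int
    history: dict = field(default_factory=lambda: {"train_loss": [], "val_loss": []})
    trained: bool = False

    def save(self, path: str | Path) -> None:
        """Single-file .npz weight store with the architecture as JSON metadata."""
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        weights = {f"w{i}": w for i, w in enumerate(self.network.get_weights())}
        meta = {
            "architecture": asdict(self.architecture),
            "input_length": self.input_length,
            "seed": self.seed,
            "history": self.history,
            "trained": self.trained,
        }
        np.savez_compressed(path, meta=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8), **weights)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        data = np.load(Path(path))
        meta = json.loads(bytes(data["meta"]).decode())
        arch = ArchitectureConfig.from_json(json.dumps(meta["architecture"]))
        model = build_model(arch, meta["input_length"], seed=meta["seed"])
        weights = [data[f"w{i}"] for i in range(len(model.network.params()))]
        model.network.set_weights(weights)
        model.history = meta["history"]
        model.trained = meta["trained"]
        return model


def _flat_length(arch: ArchitectureConfig, input_length: int) -> int:
    length = input_length
    for _f, _k, p in arch.conv_blocks:
        length //= p
        if length < 1:
            raise ModelError(
                f"input length {input_length} too short for pooling schedule "
                f"{[b[2] for b in arch.conv_blocks]}"
            )
    return length * arch.conv_blocks[-1][0]


def build_model(arch: ArchitectureConfig, input_length: int, seed: int = 0) -> TrainedModel:
    """Assemble an untrained network from the architecture description."""
    rng = np.random.default_rng(seed)
    layers = []
    in_ch = 1
    for filters, kernel, pool in arch.conv_blocks:
        layers += [Conv1D(in_ch, filters, kernel, rng), ReLU(), MaxPool1D(pool)]
        in_ch = filters
    layers += [
        Flatten(),
        Dense(_flat_length(arch, input_length), arch.dense_units, rng),
        ReLU(),
        Dropout(arch.dropout),
        Dense(arch.dense_units, arch.n_outputs, rng),
    ]
    return TrainedModel(arch, Network(layers), input_length, seed)


def _as_matrix(data) -> np.ndarray:
    if isinstance(data, SimDataset):
        return data.X
    if isinstance(data, SpectrumSet):
        return data.matrix()
    return np.asarray(data, dtype=float)


def _targets_for(head: str, ds: SimDataset) -> np.ndarray:
    return ds.presence.astype(float) if head == "classifier" else ds.regression_targets


def _epoch_loss(model: TrainedModel, X: np.ndarray, Y: np.ndarray, batch: int) -> float:
    """Average loss in inference mode (dropout off)."""
    total, n = 0.0, 0
    lossfn = bce_with_logits if model.architecture.head == "classifier" else mse_loss
    for i in range(0, len(X), batch):
        xb = X[i : i + batch, None, :]
        out = model.network.forward(xb, train=False)
        loss, _ = lossfn(out, Y[i : i + batch])
        total += loss * len(xb)
        n += len(xb)
    return total / n


def train(
    model: TrainedModel,
    train_set: SimDataset,
    val_set: SimDataset,
    cfg: TrainingConfig,
) -> TrainedModel:
    """Adam training with early stopping on validation loss.

    The weights of the best-validation epoch are restored at the end, so
    the returned model is never worse than its best epoch.
    """
    if train_set.X.shape[1] != model.input_length:
        raise ModelError(
            f"dataset width {train_set.X.shape[1]} != model input length {model.input_length}"
        )
    Xtr = train_set.X
    Ytr = _targets_for(model.architecture.head, train_set)
    Xva = val_set.X
    Yva = _targets_for(model.architecture.head, val_set)
    if Ytr.shape[1] != model.architecture.n_outputs:
        raise ModelError(
            f"label width {Ytr.shape[1]} does not match {model.architecture.head} head "
            f"({model.architecture.n_outputs} outputs)"
        )
    rng = np.random.default_rng(cfg.seed)
    lossfn = bce_with_logits if model.architecture.head == "classifier" else mse_loss
    opt = Adam(model.network.params(), lr=cfg.learning_rate)
    best_val = np.inf
    best_weights = model.network.get_weights()
    stale = 0
    for _epoch in range(cfg.max_epochs):
        order = rng.permutation(len(Xtr))
        running, seen = 0.0, 0
        for i in range(0, len(order), cfg.batch_size):
            idx = order[i : i + cfg.batch_size]
            xb = Xtr[idx][:, None, :]
            out = model.network.forward(xb, train=True, rng=rng)
            loss, dloss = lossfn(out, Ytr[idx])
            model.network.backward(dloss)
            opt.step(model.network.grads())
            running += loss * len(idx)
            seen += len(idx)
        val_loss = _epoch_loss(model, Xva, Yva, cfg.batch_size)
        model.history["train_loss"].append(running / seen)
        model.history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_weights = model.network.get_weights()
            stale = 0
        else:
            stale += 1
            if stale >= cfg.patience:
                break
    model.network.set_weights(best_weights)
    model.trained = True
    return model


def predict_scores(model: TrainedModel, spectra, batch: int = 256) -> np.ndarray:
    """Scores for a set of unit-max spectra.

    Classifier rows are presence probabilities in [0,1]^5; regressor rows
    are the raw 6-vector (l_1..l_5, z).
    """
    if not model.trained:
        raise ModelError("model has not been trained")
    X = _as_matrix(spectra)
    if X.ndim == 1:
        X = X[None, :]
    outs = []
    for i in range(0, len(X), batch):
        out = model.network.forward(X[i : i + batch, None, :], train=False)
        outs.append(out)
    scores = np.concatenate(outs)
    if model.architecture.head == "classifier":
        scores = sigmoid(scores)
    return scores


DEFAULT_SEARCH_SPACE: dict = {
    "filters": [(8, 16, 32), (16, 32, 64), (4, 8, 16)],
    "kernel": [7, 9, 11],
    "pool": [2, 4],
    "dense_units": [32, 64, 128],
    "dropout": [0.0, 0.2, 0.4],
}


def search_architecture(
    space: dict,
    opt_set: SimDataset,
    n_trials: int,
    seed: int,
    head: str = "classifier",
    trial_cfg: TrainingConfig | None = None,
    val_fraction: float = 0.25,
) -> ArchitectureConfig:
    """Seeded random search over a small architecture space.

    Each trial trains briefly on a split of the optimization set; the
    configuration with the lowest held-out loss wins.
    """
    if n_trials < 1:
        raise ModelError("n_trials must be at least 1")
    if not space or any(len(v) == 0 for v in space.values()):
        raise ModelError("search space must be non-empty in every dimension")
    rng = np.random.default_rng(seed)
    n_val = max(1, int(len(opt_set) * val_fraction))
    order = rng.permutation(len(opt_set))
    val_idx, tr_idx = order[:n_val], order[n_val:]

    def subset(ds: SimDataset, idx) -> SimDataset:
        return replace_dataset(ds, idx)

    tr, va = subset(opt_set, tr_idx), subset(opt_set, val_idx)
    cfg = trial_cfg or TrainingConfig(max_epochs=5, patience=4, seed=seed)
    best_loss, best_arch = np.inf, None
    for trial in range(n_trials):
        filters = space.get("filters", [(8, 16, 32)])[rng.integers(len(space.get("filters", [1])))]
        kernel = space.get("kernel", [9])[rng.integers(len(space.get("kernel", [1])))]
        pool = space.get("pool", [2])[rng.integers(len(space.get("pool", [1])))]
        dense = space.get("dense_units", [64])[rng.integers(len(space.get("dense_units", [1])))]
        drop = space.get("dropout", [0.2])[rng.integers(len(space.get("dropout", [1])))]
        arch = ArchitectureConfig(
            conv_blocks=tuple((f, kernel, pool) for f in filters),
            dense_units=dense,
            dropout=drop,
            head=head,
        )
        model = build_model(arch, opt_set.X.shape[1], seed=seed + trial)
        model = train(model, tr, va, cfg)
        loss = min(model.history["val_loss"])
        if loss < best_loss:
            best_loss, best_arch = loss, arch
    return best_arch


def replace_dataset(ds: SimDataset, idx) -> SimDataset:
    """Row-subset view of a dataset (used by the architecture search split)."""
    return SimDataset(
        X=ds.X[idx],
        contributions=ds.contributions[idx],
        presence=ds.presence[idx],
        norm_factors=ds.norm_factors[idx],
        raw_max=ds.raw_max[idx],
        grid=ds.grid,
        role=ds.role,
        seed=ds.seed,
        config=ds.config,
    )
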