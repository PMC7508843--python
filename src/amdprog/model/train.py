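"""Per-horizon training of the stacked-LSTM risk model.

Training applies the padding augmentation to the training split only; early
stopping monitors the weighted loss on a held-out 20% validation split of
the training eyes (split at the eye level — a sequence can never appear on
both sides).  Label weights default to (1, #neg/#pos, 0): class-balance
weight on progressors, zero weight on padding.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from amdprog.model.augment import augment_sequence, pad_single
from amdprog.model.encoding import EncodedSequence, FeatureSchema
from amdprog.model.loss import (
    class_balance_weights,
    loss_gradient_logits,
    weighted_cross_entropy,
)
from amdprog.model.lstm import Adam, StackedLSTM


@dataclass
class ModelConfig:
    l: int = 24
    hidden1: int = 50
    hidden2: int = 20
    lambda_weights: tuple[float, float, float] | None = None
    learning_rate: float = 1e-3
    weight_decay: float = 1e-3
    epochs: int = 200
    batch_size: int = 128
    patience: int = 10
    early_stopping_metric: str = "auc"  # "auc" | "loss" on the validation split
    val_fraction: float = 0.2
    clip_norm: float = 5.0
    seed: int = 0
    horizon_k: int = 3
    #: number of independently seeded members whose risks are averaged
    ensemble: int = 1

    def __post_init__(self) -> None:
        if self.hidden1 <= 0 or self.hidden2 <= 0:
            raise ValueError("hidden sizes must be positive")
        if self.lambda_weights is not None and self.lambda_weights[2] < 0:
            raise ValueError("padding weight must be non-negative")


@dataclass
class TrainedModel:
    model: StackedLSTM
    config: ModelConfig
    lam: tuple[float, float, float]
    history: dict[str, list[float]] = field(default_factory=dict)
    schema: FeatureSchema | None = None

    def predict_sequence(self, X: np.ndarray) -> np.ndarray:
        """Per-visit risk scores for one eye's (n, D) visit matrix.

        The many-to-many output at timestep t is the risk for the
        observation at t (inputs beyond t are never used).  Visits past the
        padded length l are scored on their trailing l-visit window.
        """
        X = np.asarray(X, dtype=float)
        n = X.shape[0]
        l = self.config.l
        m = min(n, l)
        padded, _ = pad_single(X[:m], l)
        scores = np.empty(n)
        scores[:m] = self.model.forward(padded[None])[0, :m]
        if n > l:
            windows = np.stack([X[j - l + 1: j + 1] for j in range(l, n)])
            scores[l:] = self.model.forward(windows)[:, -1]
        return scores

    def predict(self, X: np.ndarray) -> float:
        """Risk score at the last available visit."""
        return float(self.predict_sequence(X)[-1])

    # -- persistence ---------------------------------------------------------

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(directory / "weights.npz", *self.model.get_weights())
        meta = {
            "config": dataclasses.asdict(self.config),
            "lam": list(self.lam),
            "input_dim": self.model.input_dim,
            "history": self.history,
        }
        if self.schema is not None and self.schema.fitted:
            meta["schema"] = {
                "mean": self.schema.mean.tolist(),
                "std": self.schema.std.tolist(),
                "categorical_levels": {
                    k: list(v) for k, v in self.schema.categorical_levels.items()
                },
            }
        (directory / "model.json").write_text(json.dumps(meta, indent=2))
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "TrainedModel":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        cfg_dict = dict(meta["config"])
        if cfg_dict.get("lambda_weights") is not None:
            cfg_dict["lambda_weights"] = tuple(cfg_dict["lambda_weights"])
        config = ModelConfig(**cfg_dict)
        model = StackedLSTM(
            meta["input_dim"], hidden=(config.hidden1, config.hidden2), seed=config.seed
        )
        with np.load(directory / "weights.npz") as npz:
            model.set_weights([npz[k] for k in npz.files])
        schema = None
        if "schema" in meta:
            schema = FeatureSchema(
                mean=np.array(meta["schema"]["mean"]),
                std=np.array(meta["schema"]["std"]),
                categorical_levels={
                    k: tuple(v)
                    for k, v in meta["schema"]["categorical_levels"].items()
                },
            )
        return cls(
            model=model,
            config=config,
            lam=tuple(meta["lam"]),
            history=meta.get("history", {}),
            schema=schema,
        )


def _split_train_val(
    sequences: list[EncodedSequence], val_fraction: float, rng: np.random.Generator
) -> tuple[list[EncodedSequence], list[EncodedSequence]]:
    """Eye-level validation split, stratified by presence of a positive label."""
    pos = [s for s in sequences if np.any(s.y == 1)]
    neg = [s for s in sequences if not np.any(s.y == 1)]
    train: list[EncodedSequence] = []
    val: list[EncodedSequence] = []
    for group in (pos, neg):
        idx = rng.permutation(len(group))
        n_val = max(1, int(round(val_fraction * len(group)))) if len(group) > 1 else 0
        for rank, i in enumerate(idx):
            (val if rank < n_val else train).append(group[i])
    return train, val


def _check_no_eye_overlap(
    train: list[EncodedSequence], val: list[EncodedSequence]
) -> None:
    overlap = {s.eye_id for s in train} & {s.eye_id for s in val}
    if overlap:
        raise ValueError(f"eye(s) present in both train and validation: {sorted(overlap)}")


def _clip_grads(grads: list[np.ndarray], max_norm: float) -> None:
    total = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
    if total > max_norm > 0:
        scale = max_norm / total
        for g in grads:
            g *= scale


def train(
    sequences: list[EncodedSequence],
    config: ModelConfig,
    val_sequences: list[EncodedSequence] | None = None,
    schema: FeatureSchema | None = None,
) -> TrainedModel:
    """Train one horizon-specific model.

    ``sequences`` are the training eyes; when ``val_sequences`` is None a
    20% eye-level split is carved out internally.  Raises on degenerate
    labels (no progressor) and on eye overlap between train and validation.
    """
    if not sequences:
        raise ValueError("no training sequences")
    rng = np.random.default_rng(config.seed)

    if val_sequences is None:
        train_seqs, val_seqs = _split_train_val(sequences, config.val_fraction, rng)
    else:
        train_seqs, val_seqs = list(sequences), list(val_sequences)
    _check_no_eye_overlap(train_seqs, val_seqs)

    all_train_labels = np.concatenate([s.y for s in train_seqs])
    lam = (
        tuple(config.lambda_weights)
        if config.lambda_weights is not None
        else class_balance_weights(all_train_labels)
    )
    if not np.any(all_train_labels == 1):
        raise ValueError("degenerate labels: no progressor in training data")

    # augmentation on the training set only
    Xa_parts, Ya_parts = [], []
    for s in train_seqs:
        Xa, Ya, _ = augment_sequence(s.X, s.y, config.l)
        Xa_parts.append(Xa)
        Ya_parts.append(Ya)
    X_train = np.concatenate(Xa_parts)
    Y_train = np.concatenate(Ya_parts)

    # validation: each sequence padded once, no augmentation
    X_val = np.stack([pad_single(s.X, config.l)[0] for s in val_seqs]) if val_seqs else None
    if val_seqs:
        Y_val = np.full((len(val_seqs), config.l), 2, dtype=int)
        for i, s in enumerate(val_seqs):
            m = min(s.X.shape[0], config.l)
            Y_val[i, :m] = s.y[-m:] if s.X.shape[0] > config.l else s.y

    D = X_train.shape[2]
    model = StackedLSTM(D, hidden=(config.hidden1, config.hidden2), seed=config.seed)
    optimizer = Adam(model.params, lr=config.learning_rate)

    n = X_train.shape[0]
    history: dict[str, list[float]] = {"train_loss": [], "val_loss": [], "val_auc": []}
    use_auc = config.early_stopping_metric == "auc"
    if val_seqs:
        supervised = Y_val != 2
        # ranking needs both classes; otherwise fall back to loss monitoring
        use_auc = use_auc and len(np.unique(Y_val[supervised])) == 2
    best_score = -np.inf
    best_weights = model.get_weights()
    stale = 0
    for _epoch in range(config.epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start:start + config.batch_size]
            Xb, Yb = X_train[idx], Y_train[idx]
            yhat, cache = model.forward(Xb, return_cache=True)
            epoch_loss += weighted_cross_entropy(Yb, yhat, lam) * len(idx)
            dlogits = loss_gradient_logits(Yb, yhat, lam)
            grads = model.backward(dlogits, cache)
            if config.weight_decay:
                for p, g in zip(model.params, grads):
                    g += config.weight_decay * p
            _clip_grads(grads, config.clip_norm)
            optimizer.step(model.params, grads)
        history["train_loss"].append(epoch_loss / n)

        if val_seqs:
            yhat_val = model.forward(X_val)
            val_loss = weighted_cross_entropy(Y_val, yhat_val, lam)
            history["val_loss"].append(val_loss)
            if use_auc:
                from sklearn.metrics import roc_auc_score

                val_score = roc_auc_score(Y_val[supervised], yhat_val[supervised])
                history["val_auc"].append(float(val_score))
            else:
                val_score = -val_loss
            if val_score > best_score + 1e-6:
                best_score = val_score
                best_weights = model.get_weights()
                stale = 0
            else:
                stale += 1
                if stale >= config.patience:
                    break
        else:
            best_weights = model.get_weights()

    model.set_weights(best_weights)
    return TrainedModel(model=model, config=config, lam=lam, history=history, schema=schema)


def predict(trained: TrainedModel, X: np.ndarray) -> float:
    """Risk score in [0, 1] for an eye given its visits up to now."""
    return trained.predict(X)


@dataclass
class EnsembleModel:
    """Average of independently seeded :class:`TrainedModel` members."""

    members: list[TrainedModel]

    @property
    def config(self) -> ModelConfig:
        return self.members[0].config

    @property
    def schema(self) -> FeatureSchema | None:
        return self.members[0].schema

    @property
    def lam(self) -> tuple[float, float, float]:
        return self.members[0].lam

    @property
    def history(self) -> dict[str, list[float]]:
        return self.members[0].history

    def predict_sequence(self, X: np.ndarray) -> np.ndarray:
        return np.mean([m.predict_sequence(X) for m in self.members], axis=0)

    def predict(self, X: np.ndarray) -> float:
        return float(self.predict_sequence(X)[-1])


def train_ensemble(
    sequences: list[EncodedSequence],
    config: ModelConfig,
    schema: FeatureSchema | None = None,
) -> TrainedModel | EnsembleModel:
    """Train ``config.ensemble`` members with decorrelated seeds; a single
    member is returned unwrapped."""
    if config.ensemble <= 1:
        return train(sequences, config, schema=schema)
    members = [
        train(
            sequences,
            dataclasses.replace(config, seed=config.seed + 7919 * i, ensemble=1),
            schema=schema,
        )
        for i in range(config.ensemble)
    ]
    return EnsembleModel(members=members)
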