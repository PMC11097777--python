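"""Optimisation protocol: class-weighted cross-entropy with Adam,
plateau learning-rate halving and early stopping on validation loss.

Target trials are rare (1-4% in RSVP), so the cross-entropy is weighted
inversely to class frequency (the ``balanced`` scheme w_c = n / (2 n_c));
without it the optimiser happily predicts the majority class. A stratified
fraction of the training trials is held out as an inner validation monitor
- the test folds of any outer cross-validation are never seen here. When
the monitored loss fails to improve (strict decrease beyond a small
min-delta) for ``lr_patience`` consecutive epochs the learning rate is
multiplied by ``lr_factor``; after ``early_stop_patience`` epochs without
improvement training stops and the best-epoch parameters are restored.
Every random choice (split, shuffling, dropout) derives from one seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._nn import Adam
from .network import Network
from .preprocessing import EpochSet

LR_FLOOR = 1e-6
MIN_DELTA = 1e-5


@dataclass
class TrainConfig:
    learning_rate: float = 1e-3
    batch_size: int = 64
    max_epochs: int = 500
    lr_factor: float = 0.5
    lr_patience: int = 5
    early_stop_patience: int = 20
    class_weighting: str | tuple[float, float] = "balanced"
    validation_fraction: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.max_epochs < 1:
            raise ValueError("learning_rate, batch_size, max_epochs must be positive")
        if self.lr_patience < 1 or self.early_stop_patience < 1:
            raise ValueError("patience values must be >= 1")
        if self.early_stop_patience <= self.lr_patience:
            raise ValueError("early_stop_patience must exceed lr_patience")
        if not 0.0 < self.validation_fraction < 0.5:
            raise ValueError("validation_fraction must lie in (0, 0.5)")
        if not (self.class_weighting in ("balanced", "none")
                or (isinstance(self.class_weighting, (tuple, list))
                    and len(self.class_weighting) == 2)):
            raise ValueError("class_weighting: 'balanced', 'none' or two weights")


@dataclass
class TrainingHistory:
    train_loss: list[float] = field(default_factory=list)
    val_loss: list[float] = field(default_factory=list)
    learning_rate: list[float] = field(default_factory=list)
    best_epoch: int = 0          # 1-based epoch of the restored parameters
    best_val_loss: float = float("inf")
    stopped_early: bool = False

    @property
    def n_epochs(self) -> int:
        return len(self.train_loss)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "epoch": np.arange(1, self.n_epochs + 1),
            "train_loss": self.train_loss,
            "val_loss": self.val_loss,
            "learning_rate": self.learning_rate,
        })


def class_weights(labels) -> np.ndarray:
    """Balanced weights w_c = n_total / (2 * n_c) for classes (0, 1)."""
    labels = np.asarray(labels)
    counts = np.array([(labels == 0).sum(), (labels == 1).sum()], dtype=float)
    if (counts == 0).any():
        raise ValueError("class weights need both classes present")
    return labels.size / (2.0 * counts)


def weighted_cross_entropy(probabilities, labels, weights=(1.0, 1.0)) -> float:
    """Mean over trials of -w_y * log p_y, with a 1e-12 probability floor."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels, dtype=int)
    w = np.asarray(weights, dtype=float)
    py = np.maximum(p[np.arange(len(y)), y], 1e-12)
    return float(np.mean(-w[y] * np.log(py)))


def _ce_grad(probabilities, labels, weights) -> np.ndarray:
    """Gradient of the weighted cross-entropy w.r.t. the probabilities."""
    p = np.asarray(probabilities)
    y = np.asarray(labels, dtype=int)
    g = np.zeros_like(p)
    py = np.maximum(p[np.arange(len(y)), y], 1e-12)
    g[np.arange(len(y)), y] = -np.asarray(weights)[y] / (py * len(y))
    return g


def stratified_holdout(labels, fraction: float, rng: np.random.Generator):
    """Per-class random split; returns (train_idx, val_idx), both classes in
    both parts or a loud failure."""
    labels = np.asarray(labels)
    train, val = [], []
    for c in (0, 1):
        idx = np.flatnonzero(labels == c)
        if idx.size < 2:
            raise ValueError(
                f"class {c} has {idx.size} trial(s); cannot carve a stratified "
                "validation split")
        idx = rng.permutation(idx)
        n_val = max(1, int(round(fraction * idx.size)))
        if n_val >= idx.size:
            n_val = idx.size - 1
        val.append(idx[:n_val])
        train.append(idx[n_val:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(val))


def _eval_loss(net: Network, x: np.ndarray, y: np.ndarray, w,
               batch: int = 256) -> float:
    probs = net.predict_proba(x, batch_size=batch)
    return weighted_cross_entropy(probs, y, w)


def fit(net: Network, train_epochs: EpochSet, config: TrainConfig | None = None,
        monitor=None, verbose: bool = False):
    """Train a network in place; returns (net, TrainingHistory).

    ``monitor`` optionally replaces the monitored quantity: a callable
    ``monitor(epoch, val_loss) -> float`` (used to test the schedule logic
    with injected loss curves).
    """
    config = config or TrainConfig()
    config.validate()
    labels = np.asarray(train_epochs.labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("training requires both classes present")

    ss = np.random.SeedSequence(config.seed)
    split_rng, shuffle_rng, drop_rng = (np.random.default_rng(s)
                                        for s in ss.spawn(3))
    tr_idx, va_idx = stratified_holdout(labels, config.validation_fraction,
                                        split_rng)
    x_tr = train_epochs.epochs[tr_idx]
    y_tr = labels[tr_idx]
    x_va = train_epochs.epochs[va_idx]
    y_va = labels[va_idx]

    if config.class_weighting == "balanced":
        w = class_weights(y_tr)
    elif config.class_weighting == "none":
        w = np.ones(2)
    else:
        w = np.asarray(config.class_weighting, dtype=float)

    opt = Adam(net.named_params(), lr=config.learning_rate)
    history = TrainingHistory()
    best_state = net.get_state()
    plateau = 0
    since_best = 0
    lr = config.learning_rate

    for epoch in range(1, config.max_epochs + 1):
        opt.lr = lr
        perm = shuffle_rng.permutation(len(y_tr))
        losses = []
        for start in range(0, len(perm), config.batch_size):
            sel = perm[start:start + config.batch_size]
            if sel.size < 2:
                continue  # batch norm needs >= 2 samples in training mode
            probs = net.forward(x_tr[sel], mode="train", rng=drop_rng)
            losses.append(weighted_cross_entropy(probs, y_tr[sel], w))
            net.backward(_ce_grad(probs, y_tr[sel], w).astype(probs.dtype))
            opt.step(dict(net.net.named_grads("")))
        val_loss = _eval_loss(net, x_va, y_va, w)
        monitored = monitor(epoch, val_loss) if monitor is not None else val_loss

        history.train_loss.append(float(np.mean(losses)) if losses else float("nan"))
        history.val_loss.append(float(val_loss))
        history.learning_rate.append(lr)
        if verbose:
            print(f"epoch {epoch:4d}  train {history.train_loss[-1]:.4f}  "
                  f"val {val_loss:.4f}  lr {lr:.2e}")

        if monitored < history.best_val_loss - MIN_DELTA:
            history.best_val_loss = float(monitored)
            history.best_epoch = epoch
            best_state = net.get_state()
            plateau = 0
            since_best = 0
        else:
            plateau += 1
            since_best += 1
            if plateau >= config.lr_patience:
                lr = max(lr * config.lr_factor, LR_FLOOR)
                plateau = 0
            if since_best >= config.early_stop_patience:
                history.stopped_early = True
                break

    net.set_state(best_state)
    return net, history
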