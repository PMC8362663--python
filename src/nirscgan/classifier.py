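"""CNN task classifier over 28×28 GASF images.

Architecture (18 counted units): input, four convolution + batch-norm +
max-pool blocks (ReLU convs), flatten, two fully connected layers each
followed by dropout, and a 3-way softmax output.  Training uses
categorical cross-entropy plus an l2 kernel penalty, RMSprop, small
batches, learning-rate reduction on a validation-loss plateau, and early
stopping with best-weight restoration.

Evaluation purity is enforced structurally: the validation/test dataset
may never contain generator-produced images.

Shaped like a statsmodels model: ``GASFClassifier(train, val, config)``
holds the data; ``fit(seed)`` returns :class:`ClassifierResults` with the
trained network, per-epoch history and ``summary()``.  A small random
hyper-parameter search is provided by :func:`random_search`.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import nn
from .types import IMAGE_SIDE, N_CLASSES, ImageDataset

__all__ = ["CNNConfig", "GASFClassifier", "ClassifierResults", "SearchSpace", "random_search"]

logger = logging.getLogger(__name__)


@dataclass
class CNNConfig:
    """Classifier hyper-parameters."""

    filters: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel_size: int = 3
    dense_widths: tuple[int, int] = (128, 64)
    dropout: float = 0.3
    l2: float = 0.5
    batch_size: int = 4
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    early_stop_patience: int = 10
    max_epochs: int = 60

    def __post_init__(self) -> None:
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must lie in [0, 1)")
        if self.l2 < 0:
            raise ValueError("l2 must be non-negative")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.optimizer not in ("rmsprop", "adam"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")


def _build_network(cfg: CNNConfig, rng: np.random.Generator) -> nn.Sequential:
    k = cfg.kernel_size
    pad = k // 2
    layers: list[nn.layers.Layer] = []
    c_in, side = 1, IMAGE_SIDE
    for f in cfg.filters:
        layers += [
            nn.Conv2D(c_in, f, k, rng, stride=1, pad=pad),
            nn.BatchNorm(f),
            nn.ReLU(),
            nn.MaxPool2D(),
        ]
        c_in, side = f, side // 2
    layers.append(nn.Flatten())
    d_in = c_in * side * side
    for width in cfg.dense_widths:
        layers += [nn.Dense(d_in, width, rng), nn.ReLU(), nn.Dropout(cfg.dropout, rng)]
        d_in = width
    layers.append(nn.Dense(d_in, N_CLASSES, rng))
    return nn.Sequential(*layers)


def _l2_penalty(net: nn.Sequential, lam: float) -> float:
    if lam == 0:
        return 0.0
    total = 0.0
    for layer, name in net.param_items():
        if name in layer.decay_params:
            total += float(np.sum(layer.params[name] ** 2))
    return lam * total


def _add_l2_grads(net: nn.Sequential, lam: float) -> None:
    if lam == 0:
        return
    for layer, name in net.param_items():
        if name in layer.decay_params:
            layer.grads[name] += 2.0 * lam * layer.params[name]


class GASFClassifier:
    """Model object binding train/validation image datasets to a CNNConfig."""

    def __init__(self, train: ImageDataset, val: ImageDataset,
                 config: CNNConfig | None = None) -> None:
        if len(train) == 0 or len(val) == 0:
            raise ValueError("train and validation datasets must be non-empty")
        if val.has_generated():
            raise ValueError(
                "validation/test data must be real only; generated images are "
                "admissible in the training set alone"
            )
        self.train = train
        self.val = val
        self.config = config or CNNConfig()

    def fit(self, seed: int = 0) -> "ClassifierResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        net = _build_network(cfg, rng)
        if cfg.optimizer == "rmsprop":
            opt = nn.RMSprop(net.param_items(), lr=cfg.learning_rate)
        else:
            opt = nn.Adam(net.param_items(), lr=cfg.learning_rate)

        x_train = self.train.pixel_array().astype(np.float32)
        y_train = self.train.labels
        x_val = self.val.pixel_array().astype(np.float32)
        y_val = self.val.labels
        n = x_train.shape[0]

        history: dict[str, list[float]] = {
            "train_loss": [], "train_acc": [], "val_loss": [], "val_acc": [], "lr": [],
        }
        best_val = np.inf
        best_state = [a.copy() for a in net.state_arrays()]
        plateau_wait = early_wait = 0
        for epoch in range(cfg.max_epochs):
            order = rng.permutation(n)
            ep_loss, ep_correct = 0.0, 0
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                logits = net.forward(x_train[idx], training=True)
                loss, dlogits = nn.softmax_cross_entropy(logits, y_train[idx])
                net.backward(dlogits)
                _add_l2_grads(net, cfg.l2)
                opt.step()
                ep_loss += (loss + _l2_penalty(net, cfg.l2)) * idx.size
                ep_correct += int((logits.argmax(axis=1) == y_train[idx]).sum())
            val_logits = net.forward(x_val, training=False)
            val_loss, _ = nn.softmax_cross_entropy(val_logits, y_val)
            val_acc = float((val_logits.argmax(axis=1) == y_val).mean())

            history["train_loss"].append(ep_loss / n)
            history["train_acc"].append(ep_correct / n)
            history["val_loss"].append(val_loss)
            history["val_acc"].append(val_acc)
            history["lr"].append(opt.lr)
            if not np.isfinite(ep_loss + val_loss):
                raise RuntimeError(f"non-finite loss at epoch {epoch}")

            if val_loss < best_val - 1e-6:
                best_val = val_loss
                best_state = [a.copy() for a in net.state_arrays()]
                plateau_wait = early_wait = 0
            else:
                plateau_wait += 1
                early_wait += 1
                if plateau_wait >= cfg.plateau_patience:
                    opt.lr *= cfg.plateau_factor
                    plateau_wait = 0
                    logger.info("LR_PLATEAU epoch=%d new_lr=%.2e", epoch, opt.lr)
                if early_wait >= cfg.early_stop_patience:
                    logger.info("EARLY_STOP epoch=%d", epoch)
                    break
        net.set_state(best_state)
        return ClassifierResults(network=net, config=cfg, history=history, seed=seed)


@dataclass
class ClassifierResults:
    """Fitted classifier: network, training history, prediction, summary."""

    network: nn.Sequential
    config: CNNConfig
    history: dict[str, list[float]]
    seed: int

    def predict_proba(self, images: ImageDataset | np.ndarray) -> np.ndarray:
        """Per-class probability rows (each sums to 1; dropout off)."""
        x = images.pixel_array() if isinstance(images, ImageDataset) else np.asarray(images)
        x = x.astype(np.float32)
        if x.ndim != 4 or x.shape[1:] != (1, IMAGE_SIDE, IMAGE_SIDE):
            raise ValueError(f"expected (n, 1, 28, 28) images, got {x.shape}")
        return nn.softmax(self.network.forward(x, training=False))

    def predict(self, images: ImageDataset | np.ndarray) -> np.ndarray:
        """Hard labels: arg-max with lowest-class-code tie-break."""
        return self.predict_proba(images).argmax(axis=1)

    def weights_hash(self) -> str:
        h = hashlib.sha256()
        for arr in self.network.state_arrays():
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def summary(self) -> str:
        h = self.history
        lines = [
            "GASF CNN classifier fit",
            "=======================",
            f"conv filters:     {self.config.filters}, kernel {self.config.kernel_size}×{self.config.kernel_size}",
            f"dense widths:     {self.config.dense_widths}, dropout {self.config.dropout}",
            f"l2 strength:      {self.config.l2}",
            f"optimizer:        {self.config.optimizer}(lr={self.config.learning_rate})",
            f"epochs run:       {len(h['train_loss'])} (max {self.config.max_epochs})",
            f"seed:             {self.seed}",
        ]
        if h["val_acc"]:
            best = int(np.argmin(h["val_loss"]))
            lines += [
                f"best val loss:    {h['val_loss'][best]:.4f} (epoch {best})",
                f"val accuracy:     {h['val_acc'][best]:.4f} at best epoch",
            ]
        return "\n".join(lines)


@dataclass
class SearchSpace:
    """Candidate sets for the random hyper-parameter search."""

    dropout: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5)
    optimizer: tuple[str, ...] = ("rmsprop", "adam")
    kernel_size: tuple[int, ...] = (3, 5)
    dense_widths: tuple[tuple[int, int], ...] = ((128, 64), (64, 32), (256, 128))
    n_trials: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("dropout", "optimizer", "kernel_size", "dense_widths"):
            if not getattr(self, name):
                raise ValueError(f"candidate set {name} must be non-empty")
        if self.n_trials < 1:
            raise ValueError("n_trials must be >= 1")


def random_search(space: SearchSpace, train: ImageDataset, val: ImageDataset,
                  base_config: CNNConfig | None = None) -> tuple[CNNConfig, pd.DataFrame]:
    """Uniform random search over ``space``; best validation accuracy wins.

    Ties break toward the earlier trial.  Returns the winning config and a
    table of every trial's configuration and score.
    """
    base = base_config or CNNConfig()
    rng = np.random.default_rng(space.seed)
    rows = []
    best_acc, best_cfg = -1.0, None
    for trial in range(space.n_trials):
        cfg = replace(
            base,
            dropout=float(rng.choice(space.dropout)),
            optimizer=str(rng.choice(space.optimizer)),
            kernel_size=int(rng.choice(space.kernel_size)),
            dense_widths=tuple(space.dense_widths[rng.integers(len(space.dense_widths))]),
        )
        res = GASFClassifier(train, val, cfg).fit(seed=space.seed + trial)
        acc = float((res.predict(val) == val.labels).mean())
        rows.append({
            "trial": trial, "dropout": cfg.dropout, "optimizer": cfg.optimizer,
            "kernel_size": cfg.kernel_size, "dense_widths": cfg.dense_widths,
            "val_accuracy": acc,
        })
        if acc > best_acc:
            best_acc, best_cfg = acc, cfg
    return best_cfg, pd.DataFrame(rows)
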