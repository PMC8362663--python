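"""Conditional GAN for class-targeted synthesis of GASF images.

Two networks play the minimax game

    min_G max_D  E_x[log D(x|y)] + E_z[log(1 − D(G(z|y)))]

where ``y`` is the task label, ``x`` a real 28×28 GASF image and
``z ~ N(0, I)`` a latent vector.  At the optimum the discriminator
approaches D*(x) = p_r(x) / (p_r(x) + p_g(x)) and outputs 1/2 everywhere
once the generator matches the data distribution.

The generator maps (z, y) through a dense layer reshaped to a 7×7×128 grid
(plus a 7×7 label-embedding channel) and three transposed-convolution
layers with 4×4 kernels (7→14→28 plus a stride-1 refinement), batch-
normalized and ReLU-activated except for the tanh output.  The
discriminator is a small strided conv stack over the image plus a 28×28
label channel, ending in a single real-vs-fake logit.

Shaped like a statsmodels model: ``ConditionalGAN(dataset, config)`` holds
the data, ``fit(seed)`` returns :class:`CGANResults` carrying the trained
networks, the per-step training history and ``summary()``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .types import IMAGE_SIDE, N_CLASSES, GASFImage, ImageDataset, TaskLabel

__all__ = ["CGANConfig", "ConditionalGAN", "CGANResults", "TrainingDivergedError",
           "Generator", "Discriminator", "allocate_counts"]

logger = logging.getLogger(__name__)


class TrainingDivergedError(RuntimeError):
    """Raised when a training loss becomes non-finite; carries the history."""

    def __init__(self, message: str, history: dict[str, list[float]]) -> None:
        super().__init__(message)
        self.history = history


@dataclass
class CGANConfig:
    """Training hyper-parameters; DCGAN-convention defaults."""

    latent_dim: int = 100
    embed_dim: int = 50
    batch_size: int = 32
    steps: int = 600
    lr: float = 2e-4
    beta1: float = 0.5
    g_base_filters: int = 64
    d_base_filters: int = 32
    msssim_ceiling: float = 0.98

    def __post_init__(self) -> None:
        if self.latent_dim < 1 or self.batch_size < 1 or self.steps < 0:
            raise ValueError("latent_dim, batch_size must be >= 1 and steps >= 0")


class Generator:
    """(z, y) → 28×28 grid in (−1, 1)."""

    def __init__(self, cfg: CGANConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        f = cfg.g_base_filters
        self.embed = nn.Embedding(N_CLASSES, cfg.embed_dim, rng)
        self.label_dense = nn.Dense(cfg.embed_dim, 7 * 7, rng)
        self.z_dense = nn.Dense(cfg.latent_dim, 7 * 7 * 128, rng)
        self.z_bn = nn.BatchNorm(128)
        self.z_relu = nn.ReLU()
        self.deconv = nn.Sequential(
            nn.ConvTranspose2D(129, f, 4, rng, stride=2, crop=(1, 1, 1, 1)),   # 7 → 14
            nn.BatchNorm(f),
            nn.ReLU(),
            nn.ConvTranspose2D(f, f // 2, 4, rng, stride=2, crop=(1, 1, 1, 1)),  # 14 → 28
            nn.BatchNorm(f // 2),
            nn.ReLU(),
            nn.ConvTranspose2D(f // 2, 1, 4, rng, stride=1, crop=(1, 2, 1, 2)),  # 28 → 28
            nn.Tanh(),
        )

    def forward(self, z: np.ndarray, y: np.ndarray, training: bool = True) -> np.ndarray:
        n = z.shape[0]
        if z.shape[1] != self.cfg.latent_dim:
            raise ValueError(f"latent dim {z.shape[1]} != configured {self.cfg.latent_dim}")
        h = self.z_dense.forward(z, training).reshape(n, 128, 7, 7)
        h = self.z_relu.forward(self.z_bn.forward(h, training), training)
        lab = self.label_dense.forward(self.embed.forward(y, training), training)
        lab = lab.reshape(n, 1, 7, 7)
        x = np.concatenate([h, lab], axis=1)
        return self.deconv.forward(x, training)

    def backward(self, dout: np.ndarray) -> None:
        dx = self.deconv.backward(dout)
        dh, dlab = dx[:, :128], dx[:, 128:]
        dlab = self.label_dense.backward(dlab.reshape(dlab.shape[0], -1))
        self.embed.backward(dlab)
        dh = self.z_bn.backward(self.z_relu.backward(dh))
        self.z_dense.backward(dh.reshape(dh.shape[0], -1))

    def param_items(self):
        for layer in (self.embed, self.label_dense, self.z_dense, self.z_bn):
            for name in layer.params:
                yield layer, name
        yield from self.deconv.param_items()

    def state_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in (self.embed, self.label_dense, self.z_dense):
            out.extend(layer.params.values())
        out.extend(self.z_bn.params.values())
        out.extend([self.z_bn.running_mean, self.z_bn.running_var])
        out.extend(self.deconv.state_arrays())
        return out


class Discriminator:
    """(image in (−1,1) scale, y) → real-vs-fake logit."""

    def __init__(self, cfg: CGANConfig, rng: np.random.Generator) -> None:
        self.cfg = cfg
        f = cfg.d_base_filters
        self.embed = nn.Embedding(N_CLASSES, cfg.embed_dim, rng)
        self.label_dense = nn.Dense(cfg.embed_dim, IMAGE_SIDE * IMAGE_SIDE, rng)
        self.conv = nn.Sequential(
            nn.Conv2D(2, f, 4, rng, stride=2, pad=1),      # 28 → 14
            nn.LeakyReLU(0.2),
            nn.Conv2D(f, 2 * f, 4, rng, stride=2, pad=1),  # 14 → 7
            nn.LeakyReLU(0.2),
            nn.Flatten(),
            nn.Dense(2 * f * 7 * 7, 1, rng),
        )

    def forward(self, images: np.ndarray, y: np.ndarray, training: bool = True) -> np.ndarray:
        if images.shape[1:] != (1, IMAGE_SIDE, IMAGE_SIDE):
            raise ValueError(f"expected (n, 1, 28, 28) images, got {images.shape}")
        n = images.shape[0]
        lab = self.label_dense.forward(self.embed.forward(y, training), training)
        lab = lab.reshape(n, 1, IMAGE_SIDE, IMAGE_SIDE)
        x = np.concatenate([images, lab], axis=1)
        return self.conv.forward(x, training).ravel()

    def probability(self, images: np.ndarray, y: np.ndarray) -> np.ndarray:
        """D's real-probability output, strictly inside (0, 1)."""
        logit = self.forward(images, y, training=False)
        return 1.0 / (1.0 + np.exp(-np.clip(logit, -60, 60)))

    def backward(self, dlogit: np.ndarray) -> np.ndarray:
        """Backprop; returns the gradient w.r.t. the *image* input."""
        dx = self.conv.backward(dlogit.reshape(-1, 1))
        dimg, dlab = dx[:, :1], dx[:, 1:]
        dlab = self.label_dense.backward(dlab.reshape(dlab.shape[0], -1))
        self.embed.backward(dlab)
        return dimg

    def param_items(self):
        for layer in (self.embed, self.label_dense):
            for name in layer.params:
                yield layer, name
        yield from self.conv.param_items()

    def state_arrays(self) -> list[np.ndarray]:
        out = []
        for layer in (self.embed, self.label_dense):
            out.extend(layer.params.values())
        out.extend(self.conv.state_arrays())
        return out


def allocate_counts(n_train_real: int, fraction: float) -> list[int]:
    """Class-balanced allocation of ``round(fraction × n_train_real)`` images.

    The remainder after equal division is assigned round-robin by class code
    (RHT, then LHT, then FT).
    """
    if fraction < 0:
        raise ValueError("fraction must be non-negative")
    total = int(np.floor(fraction * n_train_real + 0.5))
    base, rem = divmod(total, N_CLASSES)
    return [base + (1 if c < rem else 0) for c in range(N_CLASSES)]


class ConditionalGAN:
    """Model object: a training dataset plus hyper-parameters; ``fit`` trains."""

    def __init__(self, train: ImageDataset, config: CGANConfig | None = None) -> None:
        if len(train) == 0:
            raise ValueError("training dataset is empty")
        counts = train.class_counts()
        missing = [lab.name for lab, c in counts.items() if c == 0]
        if missing:
            raise ValueError(f"all classes must be represented; missing {missing}")
        self.train = train
        self.config = config or CGANConfig()

    def fit(self, seed: int = 0) -> "CGANResults":
        cfg = self.config
        rng = np.random.default_rng(seed)
        gen = Generator(cfg, rng)
        disc = Discriminator(cfg, rng)
        opt_g = nn.Adam(gen.param_items(), lr=cfg.lr, beta1=cfg.beta1)
        opt_d = nn.Adam(disc.param_items(), lr=cfg.lr, beta1=cfg.beta1)

        # Real images are stored in [0, 1]; the networks work on (−1, 1).
        x_real_all = (2.0 * self.train.pixel_array() - 1.0).astype(np.float32)
        y_real_all = self.train.labels
        n_real = x_real_all.shape[0]
        bs = min(cfg.batch_size, n_real)

        history: dict[str, list[float]] = {
            "d_loss_real": [], "d_loss_fake": [], "d_loss": [],
            "g_loss": [], "d_acc": [],
        }
        for step in range(cfg.steps):
            idx = rng.choice(n_real, size=bs, replace=False)
            x_real, y_real = x_real_all[idx], y_real_all[idx]

            # --- discriminator update: real batch target 1, fake batch target 0
            z = rng.standard_normal((bs, cfg.latent_dim)).astype(np.float32)
            y_fake = rng.integers(0, N_CLASSES, size=bs)
            x_fake = gen.forward(z, y_fake, training=True)

            logit_r = disc.forward(x_real, y_real, training=True)
            loss_r, dlogit_r = nn.bce_with_logits(logit_r, np.ones(bs))
            disc.backward(dlogit_r)
            real_grads = [layer.grads[name].copy() for layer, name in disc.param_items()]

            logit_f = disc.forward(x_fake, y_fake, training=True)
            loss_f, dlogit_f = nn.bce_with_logits(logit_f, np.zeros(bs))
            disc.backward(dlogit_f)
            for (layer, name), g in zip(disc.param_items(), real_grads):
                layer.grads[name] += g
            opt_d.step()

            acc = 0.5 * ((logit_r > 0).mean() + (logit_f <= 0).mean())

            # --- generator update: non-saturating, maximize D(G(z|y))
            z = rng.standard_normal((bs, cfg.latent_dim)).astype(np.float32)
            y_g = rng.integers(0, N_CLASSES, size=bs)
            x_g = gen.forward(z, y_g, training=True)
            logit_g = disc.forward(x_g, y_g, training=True)
            loss_g, dlogit_g = nn.bce_with_logits(logit_g, np.ones(bs))
            dimg = disc.backward(dlogit_g)
            gen.backward(dimg)
            opt_g.step()

            history["d_loss_real"].append(loss_r)
            history["d_loss_fake"].append(loss_f)
            history["d_loss"].append(loss_r + loss_f)
            history["g_loss"].append(loss_g)
            history["d_acc"].append(float(acc))
            if not np.isfinite(loss_r + loss_f + loss_g):
                raise TrainingDivergedError(
                    f"non-finite loss at step {step}", history
                )
        return CGANResults(generator=gen, discriminator=disc, config=cfg,
                           history=history, seed=seed, n_train_real=n_real)


@dataclass
class CGANResults:
    """Fitted CGAN: trained networks, training history and synthesis."""

    generator: Generator
    discriminator: Discriminator
    config: CGANConfig
    history: dict[str, list[float]]
    seed: int
    n_train_real: int
    latent_prior: str = "standard_normal"

    def generate(self, labels: np.ndarray, seed: int = 0) -> np.ndarray:
        """Raw (n, 1, 28, 28) generator output mapped to [0, 1]."""
        labels = np.asarray(labels, dtype=int)
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((labels.size, self.config.latent_dim)).astype(np.float32)
        out = self.generator.forward(z, labels, training=False)
        return np.clip((out + 1.0) / 2.0, 0.0, 1.0)

    def synthesize(self, n_train_real: int | None = None, fraction: float = 1.0,
                   seed: int = 0, check_diversity: bool = True) -> ImageDataset:
        """Class-balanced dataset of ``round(fraction × n_train_real)`` images.

        Generated pixels are mapped from the tanh range (−1, 1) to [0, 1] and
        tagged ``provenance='generated'``.  A mean pairwise MS-SSIM above the
        configured ceiling within any class raises a mode-collapse warning.
        """
        if n_train_real is None:
            n_train_real = self.n_train_real
        counts = allocate_counts(n_train_real, fraction)
        labels = np.concatenate(
            [np.full(c, code, dtype=int) for code, c in enumerate(counts)]
        ) if sum(counts) else np.zeros(0, dtype=int)
        pixels = self.generate(labels, seed=seed) if labels.size else np.zeros((0, 1, 28, 28))
        images = [
            GASFImage(pixels=pixels[i, 0], label=TaskLabel(int(labels[i])),
                      provenance="generated")
            for i in range(labels.size)
        ]
        ds = ImageDataset(images, split="train")
        if check_diversity and labels.size >= 2:
            from .evaluation import diversity_report

            rep = diversity_report(ds, max_pairs=50, seed=seed)
            for lab, score in rep.items():
                if score > self.config.msssim_ceiling:
                    warnings.warn(
                        f"MODE_COLLAPSE_SUSPECT class {lab.name}: mean pairwise "
                        f"MS-SSIM {score:.3f} exceeds ceiling {self.config.msssim_ceiling}"
                    )
        return ds

    def summary(self) -> str:
        h = self.history
        lines = [
            "Conditional GAN fit",
            "===================",
            f"training images (real): {self.n_train_real}",
            f"latent prior:           {self.latent_prior}(dim={self.config.latent_dim})",
            f"steps × batch:          {len(h['g_loss'])} × {self.config.batch_size}",
            f"optimizer:              Adam(lr={self.config.lr}, beta1={self.config.beta1})",
            f"seed:                   {self.seed}",
        ]
        if h["g_loss"]:
            lines += [
                f"final G loss:           {h['g_loss'][-1]:.4f}",
                f"final D loss:           {h['d_loss'][-1]:.4f}",
                f"final D accuracy:       {h['d_acc'][-1]:.3f}  (0.5 at equilibrium)",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        """Persist all network state to a single ``.npz`` archive."""
        arrays = {"format_version": np.array([1])}
        for i, arr in enumerate(self.generator.state_arrays()):
            arrays[f"g_{i}"] = arr
        for i, arr in enumerate(self.discriminator.state_arrays()):
            arrays[f"d_{i}"] = arr
        np.savez(path, **arrays)
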