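"""Metrics, image-diversity diagnostics and the augmentation-fraction sweep.

Classification is scored with the 3×3 confusion matrix (rows = actual,
columns = predicted, class order RHT/LHT/FT), overall accuracy
(trace/total, the multi-class reduction of (TP+TN)/(TP+FP+TN+FN)),
column-wise per-class precision, and one-vs-rest AUROC with ties counted
one half, macro-averaged.

Generator output is audited with mean pairwise multi-scale structural
similarity (MS-SSIM) within each class: values near 1 mean the generator
emits near-identical images — the signature of mode collapse.

The augmentation sweep trains the CNN on real data plus a growing
fraction of CGAN-generated images (0%, 10%, …, 110% of the real training
count) and evaluates each step on real test data only.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from sklearn.metrics import roc_auc_score

from .cgan import CGANConfig, CGANResults, ConditionalGAN
from .classifier import CNNConfig, GASFClassifier
from .types import N_CLASSES, GASFImage, ImageDataset, TaskLabel

__all__ = [
    "confusion_matrix", "accuracy", "precision_per_class", "auroc_ovr",
    "ms_ssim", "diversity_report", "EvalReport", "evaluate", "SweepReport",
    "augmentation_sweep", "relaxation_schedule", "DEFAULT_FRACTIONS",
]

logger = logging.getLogger(__name__)

DEFAULT_FRACTIONS: tuple[float, ...] = tuple(np.round(np.arange(0, 1.2, 0.1), 10))


# ---------------------------------------------------------------- metrics

def confusion_matrix(actual, predicted) -> np.ndarray:
    """3×3 count matrix; rows = actual class, columns = predicted class."""
    a = np.asarray(actual, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if a.shape != p.shape or a.size == 0:
        raise ValueError("actual and predicted must be equal-length, non-empty")
    cm = np.zeros((N_CLASSES, N_CLASSES), dtype=int)
    np.add.at(cm, (a, p), 1)
    return cm


def accuracy(cm: np.ndarray) -> float:
    """Overall accuracy in percent: 100 × trace / total."""
    cm = np.asarray(cm)
    total = cm.sum()
    if total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * float(np.trace(cm)) / float(total)


def precision_per_class(cm: np.ndarray) -> np.ndarray:
    """Column-wise precision per class; NaN (with a warning) for empty columns."""
    cm = np.asarray(cm, dtype=float)
    if cm.sum() == 0:
        raise ValueError("confusion matrix is empty")
    col = cm.sum(axis=0)
    out = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        if col[c] == 0:
            warnings.warn(f"PRECISION_UNDEFINED class {TaskLabel(c).name}: no predictions")
        else:
            out[c] = cm[c, c] / col[c]
    return out


def auroc_ovr(actual, probabilities) -> tuple[np.ndarray, float]:
    """One-vs-rest AUROC per class plus the unweighted macro average.

    Per class c the statistic is the probability that a random class-c
    sample outscores a random rest sample on probability column c, ties
    counted one half.
    """
    y = np.asarray(actual, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 2 or p.shape[0] != y.size or p.shape[1] != N_CLASSES:
        raise ValueError("probabilities must be (n_samples, 3) aligned with labels")
    present = np.unique(y)
    if present.size < 2:
        raise ValueError("AUROC needs at least two classes present")
    per_class = np.full(N_CLASSES, np.nan)
    for c in range(N_CLASSES):
        pos = y == c
        if pos.any() and (~pos).any():
            per_class[c] = roc_auc_score(pos.astype(int), p[:, c])
    macro = float(np.nanmean(per_class))
    return per_class, macro


# ---------------------------------------------------------- MS-SSIM

_MSSSIM_WEIGHTS = np.array([0.0448, 0.2856, 0.3001, 0.2363, 0.1333])


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    ax = np.arange(size) - (size - 1) / 2.0
    g = np.exp(-(ax**2) / (2.0 * sigma**2))
    win = np.outer(g, g)
    return win / win.sum()


def _ssim_maps(a: np.ndarray, b: np.ndarray, win: np.ndarray,
               data_range: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel luminance and contrast-structure maps of SSIM (valid region)."""
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    mu_a = fftconvolve(a, win, mode="valid")
    mu_b = fftconvolve(b, win, mode="valid")
    saa = fftconvolve(a * a, win, mode="valid") - mu_a**2
    sbb = fftconvolve(b * b, win, mode="valid") - mu_b**2
    sab = fftconvolve(a * b, win, mode="valid") - mu_a * mu_b
    lum = (2 * mu_a * mu_b + c1) / (mu_a**2 + mu_b**2 + c1)
    cs = (2 * sab + c2) / (saa + sbb + c2)
    return lum, cs


def ssim_index(a: np.ndarray, b: np.ndarray, window_size: int = 11) -> float:
    """Plain single-scale SSIM: mean of the per-pixel l·cs product map."""
    lum, cs = _ssim_maps(np.asarray(a, float), np.asarray(b, float),
                         _gaussian_window(window_size))
    return float((lum * cs).mean())


def _downsample2(x: np.ndarray) -> np.ndarray:
    """2×2 block means followed by dyadic decimation (standard MS-SSIM step)."""
    h, w = x.shape
    h2, w2 = h // 2, w // 2
    return x[: 2 * h2, : 2 * w2].reshape(h2, 2, w2, 2).mean(axis=(1, 3))


def ms_ssim(a: GASFImage | np.ndarray, b: GASFImage | np.ndarray,
            window_size: int = 11) -> float:
    """Multi-scale structural similarity of two equal-shape images in [0, 1].

    Uses the standard 5-scale exponent vector, truncated to the scales whose
    side length still accommodates the Gaussian window (for 28×28 inputs this
    keeps 2 scales) with the retained exponents renormalized to sum to 1.
    Symmetric in its arguments; identical images score 1.
    """
    x = a.pixels if isinstance(a, GASFImage) else np.asarray(a, dtype=float)
    y = b.pixels if isinstance(b, GASFImage) else np.asarray(b, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"image shapes differ: {x.shape} vs {y.shape}")
    n_scales = 0
    side = min(x.shape)
    while n_scales < _MSSSIM_WEIGHTS.size and side >= window_size:
        n_scales += 1
        side //= 2
    if n_scales == 0:
        raise ValueError(f"images too small for window size {window_size}")
    weights = _MSSSIM_WEIGHTS[:n_scales] / _MSSSIM_WEIGHTS[:n_scales].sum()
    win = _gaussian_window(window_size)
    value = 1.0
    for scale in range(n_scales):
        lum_map, cs_map = _ssim_maps(x, y, win)
        lum, cs = float(lum_map.mean()), float(cs_map.mean())
        if scale == n_scales - 1:
            value *= np.sign(lum * cs) * np.abs(lum * cs) ** weights[scale]
        else:
            value *= np.sign(cs) * np.abs(cs) ** weights[scale]
            x, y = _downsample2(x), _downsample2(y)
    return float(np.clip(value, 0.0, 1.0))


def diversity_report(generated: ImageDataset, max_pairs: int = 200,
                     seed: int = 0) -> dict[TaskLabel, float]:
    """Mean pairwise MS-SSIM within each generated class.

    Classes with fewer than two images are skipped with a warning; when a
    class has more than ``max_pairs`` unordered pairs a seeded subsample of
    that size is scored instead.
    """
    rng = np.random.default_rng(seed)
    report: dict[TaskLabel, float] = {}
    for lab in TaskLabel:
        imgs = [im for im in generated.images if im.label == lab]
        if len(imgs) < 2:
            if imgs:
                warnings.warn(f"DIVERSITY_SKIPPED class {lab.name}: fewer than 2 images")
            continue
        pairs = [(i, j) for i in range(len(imgs)) for j in range(i + 1, len(imgs))]
        if len(pairs) > max_pairs:
            sel = rng.choice(len(pairs), size=max_pairs, replace=False)
            pairs = [pairs[k] for k in sel]
        report[lab] = float(np.mean([ms_ssim(imgs[i], imgs[j]) for i, j in pairs]))
    return report


# ---------------------------------------------------------- reports

def _fingerprint(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


@dataclass
class EvalReport:
    """Scores of one classifier evaluation on real test data."""

    accuracy_pct: float
    precision: np.ndarray
    auroc_per_class: np.ndarray
    auroc_macro: float
    cm: np.ndarray
    n_train: int
    n_test: int
    config_fingerprint: str
    seed: int

    def to_dict(self) -> dict:
        return {
            "accuracy_pct": self.accuracy_pct,
            "precision": [None if np.isnan(v) else float(v) for v in self.precision],
            "auroc_per_class": [None if np.isnan(v) else float(v) for v in self.auroc_per_class],
            "auroc_macro": self.auroc_macro,
            "confusion_matrix": self.cm.tolist(),
            "n_train": self.n_train,
            "n_test": self.n_test,
            "config_fingerprint": self.config_fingerprint,
            "seed": self.seed,
        }


def evaluate(results, test: ImageDataset, n_train: int = 0, seed: int = 0) -> EvalReport:
    """Score fitted classifier ``results`` on a real-only test set."""
    if test.has_generated():
        raise ValueError("test set contains generated images; evaluation must be real-only")
    proba = results.predict_proba(test)
    pred = proba.argmax(axis=1)
    cm = confusion_matrix(test.labels, pred)
    per_class, macro = auroc_ovr(test.labels, proba)
    return EvalReport(
        accuracy_pct=accuracy(cm),
        precision=precision_per_class(cm),
        auroc_per_class=per_class,
        auroc_macro=macro,
        cm=cm,
        n_train=n_train,
        n_test=len(test),
        config_fingerprint=_fingerprint(vars(results.config)),
        seed=seed,
    )


def relaxation_schedule(fraction: float, l2_start: float = 0.5, l2_end: float = 0.01,
                        dropout_start: float = 0.4, dropout_end: float = 0.2,
                        max_fraction: float = 1.1) -> tuple[float, float]:
    """Regularization relaxed linearly as generated data grows.

    At fraction 0 the training pool is smallest, so regularization is
    strictest (l2 = 0.5); by the largest fraction it relaxes to l2 = 0.01.
    Returns ``(l2, dropout)`` for the given fraction.
    """
    t = min(max(fraction / max_fraction, 0.0), 1.0)
    return (l2_start + (l2_end - l2_start) * t,
            dropout_start + (dropout_end - dropout_start) * t)


@dataclass
class SweepReport:
    """Ordered per-fraction results of the augmentation sweep."""

    rows: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_json(self, path=None) -> str:
        payload = json.dumps({"schema_version": 1, "rows": self.rows}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def render_table(self) -> str:
        """Text table mirroring the amount-of-data / accuracy / AUROC layout."""
        lines = [f"{'Amount of data':<34}{'Accuracy%':>10}{'Avg AUROC':>11}"]
        for row in self.rows:
            f = row["fraction"]
            name = "Original data set" if f == 0 else f"Real data + {round(f * 100)}% generated data"
            if row.get("failed"):
                lines.append(f"{name:<34}{'failed':>10}{'-':>11}")
            else:
                lines.append(f"{name:<34}{row['accuracy_pct']:>10.2f}{row['auroc_macro']:>11.3f}")
        return "\n".join(lines)


def augmentation_sweep(
    real_train: ImageDataset,
    real_test: ImageDataset,
    cgan_config: CGANConfig | None = None,
    cnn_config: CNNConfig | None = None,
    fractions: tuple[float, ...] = DEFAULT_FRACTIONS,
    seed: int = 0,
    cgan_results: CGANResults | None = None,
) -> SweepReport:
    """Train-with-augmentation sweep over generated-data fractions.

    The CGAN is trained once on the real training images (unless a fitted
    ``cgan_results`` is supplied).  For each fraction f the sweep synthesizes
    ``round(f × n_train)`` class-balanced images, trains the CNN on
    real ∪ generated under the step's relaxed regularization, and evaluates
    on the real test set only.  A failed step records a failure row and the
    sweep continues.
    """
    if real_train.has_generated() or real_test.has_generated():
        raise ValueError("sweep inputs must be real images only")
    fractions = tuple(fractions)
    if any(b <= a for a, b in zip(fractions, fractions[1:])):
        raise ValueError("fractions must be strictly increasing")
    cnn_config = cnn_config or CNNConfig()
    if cgan_results is None:
        cgan_results = ConditionalGAN(real_train, cgan_config or CGANConfig()).fit(seed=seed)
    n_train = len(real_train)

    report = SweepReport()
    for step, f in enumerate(fractions):
        l2, dropout = relaxation_schedule(f, l2_start=cnn_config.l2,
                                          dropout_start=cnn_config.dropout)
        step_cfg = CNNConfig(**{**vars(cnn_config), "l2": l2, "dropout": dropout})
        try:
            generated = cgan_results.synthesize(n_train, f, seed=seed + 1000 + step)
            pool = ImageDataset.concat(real_train, generated, split="train")
            fitted = GASFClassifier(pool, real_test, step_cfg).fit(seed=seed + 2000 + step)
            rep = evaluate(fitted, real_test, n_train=len(pool), seed=seed)
            report.rows.append({
                "fraction": float(f),
                "n_generated": len(generated),
                "n_train_total": len(pool),
                "accuracy_pct": rep.accuracy_pct,
                "auroc_macro": rep.auroc_macro,
                "precision": rep.to_dict()["precision"],
                "confusion_matrix": rep.cm.tolist(),
                "l2": l2,
                "dropout": dropout,
                "seed": seed,
                "config_fingerprint": rep.config_fingerprint,
                "test_real_only": not real_test.has_generated(),
            })
        except Exception as exc:  # noqa: BLE001 — a failed step must not kill the sweep
            logger.exception("SWEEP_STEP_FAILED fraction=%.2f", f)
            report.rows.append({"fraction": float(f), "failed": True, "error": str(exc)})
    return report
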