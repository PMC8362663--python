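"""End-to-end orchestration: simulate → preprocess → encode → split → sweep.

Every stage's randomness derives from the run seed, so rerunning an
identical configuration reproduces every artifact bit-for-bit.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import io
from .cgan import CGANConfig
from .classifier import CNNConfig
from .config import RunConfig
from .evaluation import SweepReport, augmentation_sweep
from .gaf import encode_epoch
from .preprocess import (
    bandpass,
    baseline_correct,
    extract_epochs,
    kernel_pca_reduce,
    select_channel,
)
from .synthgen import SimConfig, generate_recording
from .types import Epoch, ImageDataset, Recording

__all__ = ["run_pipeline", "recording_to_images", "stratified_split"]

logger = logging.getLogger(__name__)


def recording_to_images(recording: Recording, config: RunConfig) -> tuple[ImageDataset, int]:
    """Preprocess a recording and encode every epoch as a GASF image.

    Returns the image dataset (in epoch order) and the selected channel.
    With ``encode.source = 'kpca1'`` the first kernel-PCA component of the
    standardized window-mean features replaces the raw channel series as
    the encoded stream.
    """
    filtered = bandpass(recording, config.filter.low, config.filter.high, config.filter.order)
    epochs = extract_epochs(filtered, config.epochs.window)
    epochs = [baseline_correct(ep, config.epochs.baseline) for ep in epochs]
    if not epochs:
        raise ValueError("no complete epochs could be extracted")
    channel = select_channel(epochs, config.epochs.feature_windows)
    logger.info("CHANNEL_SELECTED index=%d", channel)

    if config.encode.source == "kpca1":
        series_list = _kpca1_series(epochs, config, seed=0)
        images = [
            encode_epoch(ep, channel, series=s) for ep, s in zip(epochs, series_list)
        ]
    else:
        images = [
            encode_epoch(ep, channel, config.encode.chromophore) for ep in epochs
        ]
    return ImageDataset(images), channel


def _kpca1_series(epochs: list[Epoch], config: RunConfig, seed: int) -> list[np.ndarray]:
    """First kernel-PCA component as a 1-D series per epoch.

    Per-timepoint channel vectors (post-onset ΔHbO) are pooled over epochs;
    a 1-component kernel PCA is fitted on a seeded subsample of them and
    every epoch's timepoints are projected, yielding one de-correlated
    component series per epoch in place of a single raw channel.
    """
    from .preprocess import FeatureMatrix

    onset = int(round(-epochs[0].t0_offset * epochs[0].sampling_rate))
    mats = [ep.hbo[:, onset:].T for ep in epochs]  # (time, channels) each
    pooled = np.vstack(mats)
    rng = np.random.default_rng(seed)
    n_fit = min(1000, pooled.shape[0])
    sample = pooled[rng.choice(pooled.shape[0], size=n_fit, replace=False)]
    names = [f"ch{c:02d}" for c in range(sample.shape[1])]
    fm = FeatureMatrix(sample, names, np.zeros(n_fit, dtype=int))
    _, model = kernel_pca_reduce(fm, n_components=1)
    out = []
    for m in mats:
        fm_ep = FeatureMatrix(m, names, np.zeros(m.shape[0], dtype=int))
        scores, _ = kernel_pca_reduce(fm_ep, model)
        out.append(scores[:, 0])
    return out


def stratified_split(dataset: ImageDataset, test_per_class: int, seed: int
                     ) -> tuple[ImageDataset, ImageDataset]:
    """Seeded per-class split; the test set gets ``test_per_class`` images/class."""
    rng = np.random.default_rng(seed)
    labels = dataset.labels
    test_idx: list[int] = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        if members.size <= test_per_class:
            raise ValueError(
                f"class {c} has only {members.size} images; cannot hold out "
                f"{test_per_class}"
            )
        test_idx.extend(rng.choice(members, size=test_per_class, replace=False))
    test_mask = np.zeros(len(dataset), dtype=bool)
    test_mask[test_idx] = True
    train = dataset.subset(np.flatnonzero(~test_mask))
    test = dataset.subset(np.flatnonzero(test_mask))
    train.split, test.split = "train", "test"
    return train, test


def run_pipeline(config: RunConfig, outdir=None) -> SweepReport:
    """Execute the full pipeline under ``config``; optionally write artifacts."""
    out = Path(outdir) if outdir is not None else None
    sim_cfg = SimConfig(seed=config.seed, **config.sim.model_dump())
    recording = generate_recording(sim_cfg)
    if out:
        io.write_recording(recording, out / "recording")

    images, channel = recording_to_images(recording, config)
    train, test = stratified_split(images, config.split.test_per_class, seed=config.seed + 1)
    if out:
        io.write_images(train, out / "images_train")
        io.write_images(test, out / "images_test")

    report = augmentation_sweep(
        train, test,
        cgan_config=CGANConfig(**config.cgan.model_dump()),
        cnn_config=CNNConfig(**config.cnn.model_dump()),
        fractions=config.sweep.fractions,
        seed=config.seed + 2,
    )
    for row in report.rows:
        row["selected_channel"] = channel
        row["run_config_fingerprint"] = config.fingerprint()
    if out:
        report.to_json(out / "sweep_report.json")
    return report
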