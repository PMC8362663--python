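"""Shared fixtures: small synthetic recordings and encoded image sets.

Session-scoped where construction is expensive; everything is seeded so
the suite is deterministic.
"""

from __future__ import annotations

import numpy as np
import pytest

import nirscgan as ng
from nirscgan.gaf import gasf, rescale_unit
from nirscgan.types import GASFImage, ImageDataset, TaskLabel


@pytest.fixture(scope="session")
def small_recording() -> ng.Recording:
    """Separable benchmark recording: 12 trials, default noise levels."""
    return ng.generate_recording(ng.SimConfig(n_trials_per_class=4, seed=11))


@pytest.fixture(scope="session")
def noiseless_config() -> ng.SimConfig:
    return ng.SimConfig(
        n_trials_per_class=1,
        noise_amplitudes={"cardiac": 0, "respiration": 0, "mayer": 0, "drift": 0, "white": 0},
        iti_jitter=0.0,
        seed=0,
    )


@pytest.fixture(scope="session")
def benchmark_epochs(small_recording) -> list[ng.Epoch]:
    filtered = ng.bandpass(small_recording)
    return [ng.baseline_correct(ep) for ep in ng.extract_epochs(filtered)]


def make_template_images(n_per_class: int, noise: float, seed: int) -> ImageDataset:
    """Three smooth class templates GASF-encoded with per-image jitter."""
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, 28)
    templates = [
        np.exp(-((t - 0.25 - 0.2 * c) ** 2) / 0.02) * (1.0 if c < 2 else -1.0)
        + 0.3 * np.sin(2 * np.pi * (c + 1) * t)
        for c in range(3)
    ]
    images = []
    for c in range(3):
        for _ in range(n_per_class):
            series = templates[c] + noise * rng.standard_normal(28)
            m = (gasf(rescale_unit(series)) + 1.0) / 2.0
            images.append(GASFImage(np.clip(m, 0.0, 1.0), TaskLabel(c)))
    return ImageDataset(images)


@pytest.fixture(scope="session")
def template_train() -> ImageDataset:
    return make_template_images(n_per_class=10, noise=0.05, seed=21)


@pytest.fixture(scope="session")
def template_val() -> ImageDataset:
    ds = make_template_images(n_per_class=5, noise=0.05, seed=22)
    ds.split = "test"
    return ds
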