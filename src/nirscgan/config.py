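"""Schema-validated run configuration (YAML-friendly, unknown keys rejected).

A single global ``seed`` fans out deterministically to every stochastic
stage (simulation, CGAN training, synthesis, classifier training, the
train/test split), so one integer reproduces an entire run.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

__all__ = ["RunConfig", "load_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SimSection(_Strict):
    n_trials_per_class: int = 40
    sampling_rate: float = 10.0
    inter_trial_interval: float = 30.0
    iti_jitter: float = 5.0
    task_duration: float = 10.0
    hrf_peak_time: float = 6.0
    effect_amplitude: float = 1.0
    cardiac_freq: float = 1.2
    respiration_freq: float = 0.3
    mayer_freq: float = 0.1
    noise_amplitudes: dict[str, float] = Field(
        default={"cardiac": 0.2, "respiration": 0.3, "mayer": 0.3, "drift": 0.5, "white": 0.1}
    )


class FilterSection(_Strict):
    low: float = 0.01
    high: float = 0.1
    order: int = 3


class EpochSection(_Strict):
    window: tuple[float, float] = (-2.0, 28.0)
    baseline: tuple[float, float] = (-1.0, 0.0)
    feature_windows: tuple[tuple[float, float], ...] = ((0, 5), (5, 10), (10, 15))


class EncodeSection(_Strict):
    source: str = "channel"  # 'channel' (selected channel) or 'kpca1'
    chromophore: str = "hbo"

    @model_validator(mode="after")
    def _check(self):
        if self.source not in ("channel", "kpca1"):
            raise ValueError("encode.source must be 'channel' or 'kpca1'")
        if self.chromophore not in ("hbo", "hbr"):
            raise ValueError("encode.chromophore must be 'hbo' or 'hbr'")
        return self


class SplitSection(_Strict):
    test_per_class: int = 10


class CGANSection(_Strict):
    latent_dim: int = 100
    embed_dim: int = 50
    batch_size: int = 32
    steps: int = 600
    lr: float = 2e-4
    beta1: float = 0.5
    g_base_filters: int = 64
    d_base_filters: int = 32
    msssim_ceiling: float = 0.98


class CNNSection(_Strict):
    filters: tuple[int, int, int, int] = (16, 32, 64, 128)
    kernel_size: int = 3
    dense_widths: tuple[int, int] = (128, 64)
    dropout: float = 0.4
    l2: float = 0.5
    batch_size: int = 4
    optimizer: str = "rmsprop"
    learning_rate: float = 1e-3
    plateau_factor: float = 0.5
    plateau_patience: int = 5
    early_stop_patience: int = 10
    max_epochs: int = 60


class SweepSection(_Strict):
    fractions: tuple[float, ...] = tuple(round(0.1 * i, 10) for i in range(12))


class RunConfig(_Strict):
    """Top-level configuration for the end-to-end pipeline."""

    seed: int
    sim: SimSection = SimSection()
    filter: FilterSection = FilterSection()
    epochs: EpochSection = EpochSection()
    encode: EncodeSection = EncodeSection()
    split: SplitSection = SplitSection()
    cgan: CGANSection = CGANSection()
    cnn: CNNSection = CNNSection()
    sweep: SweepSection = SweepSection()

    def fingerprint(self) -> str:
        import hashlib
        import json

        return hashlib.sha256(
            json.dumps(self.model_dump(), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return RunConfig(**raw)
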