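"""Core domain containers shared across the pipeline.

The pipeline operates on multichannel fNIRS concentration-change series
(ΔHbO / ΔHbR), trial-locked epochs, and 28×28 grayscale Gramian angular
summation field (GASF) images labeled with one of three motor tasks:
right-hand finger tap (RHT), left-hand finger tap (LHT) and foot tap (FT).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TaskLabel",
    "Event",
    "Recording",
    "Epoch",
    "GASFImage",
    "ImageDataset",
    "IMAGE_SIDE",
    "N_CLASSES",
]

IMAGE_SIDE = 28
N_CLASSES = 3


class TaskLabel(enum.IntEnum):
    """Motor-task class with stable integer codes used for conditioning."""

    RHT = 0
    LHT = 1
    FT = 2

    @classmethod
    def from_string(cls, s: str) -> "TaskLabel":
        try:
            return cls[s.strip().upper()]
        except KeyError:
            raise ValueError(f"unknown task label {s!r}; expected RHT, LHT or FT") from None


@dataclass(frozen=True)
class Event:
    """A single task trial: onset (s from recording start), label, duration (s)."""

    onset: float
    label: TaskLabel
    duration: float

    def __post_init__(self) -> None:
        if self.onset < 0:
            raise ValueError(f"event onset must be non-negative, got {self.onset}")
        if self.duration <= 0:
            raise ValueError(f"event duration must be positive, got {self.duration}")


@dataclass
class Recording:
    """Multichannel ΔHbO/ΔHbR series with task events.

    ``hbo`` and ``hbr`` are (channels, samples) arrays in µM-scaled arbitrary
    units.  ``channel_side`` tags each channel 'left' or 'right' so downstream
    code can reason about hemispheric lateralization of the evoked response.
    """

    hbo: np.ndarray
    hbr: np.ndarray
    sampling_rate: float
    events: list[Event] = field(default_factory=list)
    channel_side: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError(
                f"hbo shape {self.hbo.shape} != hbr shape {self.hbr.shape}"
            )
        if self.hbo.ndim != 2:
            raise ValueError("hbo/hbr must be 2-D (channels, samples)")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.channel_side and len(self.channel_side) != self.n_channels:
            raise ValueError("channel_side length must match channel count")
        onsets = [e.onset for e in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("event onsets must be strictly increasing")
        for e in self.events:
            if e.onset + e.duration > self.duration + 1e-9:
                raise ValueError(
                    f"event at {e.onset}s (+{e.duration}s) extends past recording "
                    f"end {self.duration}s"
                )

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class Epoch:
    """One baseline-referenced trial window, spanning [t0_offset, t0_offset+T)."""

    hbo: np.ndarray
    hbr: np.ndarray
    t0_offset: float
    label: TaskLabel
    sampling_rate: float

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("epoch hbo/hbr shapes differ")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    def time_axis(self) -> np.ndarray:
        """Sample times in seconds relative to task onset."""
        return self.t0_offset + np.arange(self.n_samples) / self.sampling_rate


@dataclass
class GASFImage:
    """A 28×28 grayscale image in [0, 1] with class label and provenance tag."""

    pixels: np.ndarray
    label: TaskLabel
    provenance: str = "real"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.shape != (IMAGE_SIDE, IMAGE_SIDE):
            raise ValueError(
                f"image must be {IMAGE_SIDE}×{IMAGE_SIDE}, got {self.pixels.shape}"
            )
        if self.pixels.min() < -1e-9 or self.pixels.max() > 1 + 1e-9:
            raise ValueError("pixels must lie in [0, 1]")
        if self.provenance not in ("real", "generated"):
            raise ValueError(f"provenance must be 'real' or 'generated', got {self.provenance!r}")


@dataclass
class ImageDataset:
    """Ordered collection of GASF images with an optional split tag."""

    images: list[GASFImage] = field(default_factory=list)
    split: str = ""

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)

    @property
    def labels(self) -> np.ndarray:
        return np.array([img.label for img in self.images], dtype=int)

    def class_counts(self) -> dict[TaskLabel, int]:
        counts = {lab: 0 for lab in TaskLabel}
        for img in self.images:
            counts[img.label] += 1
        return counts

    def pixel_array(self) -> np.ndarray:
        """Stack pixels into an (n, 1, 28, 28) array suitable for the networks."""
        if not self.images:
            return np.zeros((0, 1, IMAGE_SIDE, IMAGE_SIDE))
        return np.stack([img.pixels for img in self.images])[:, None, :, :]

    def has_generated(self) -> bool:
        return any(img.provenance == "generated" for img in self.images)

    def subset(self, indices) -> "ImageDataset":
        return ImageDataset([self.images[i] for i in indices], split=self.split)

    @staticmethod
    def concat(a: "ImageDataset", b: "ImageDataset", split: str = "") -> "ImageDataset":
        return ImageDataset(list(a.images) + list(b.images), split=split)
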