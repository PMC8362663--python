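"""Seeded generator of synthetic fNIRS recordings.

Emulates the statistical structure the downstream pipeline assumes about
finger/foot-tapping fNIRS data:

* task-evoked hemodynamic responses with hemispheric lateralization — a
  right-hand tap (RHT) raises ΔHbO over the *left* (contralateral)
  hemisphere while ΔHbR dips; a left-hand tap mirrors this; a foot tap
  lowers ΔHbO and raises ΔHbR over both hemispheres;
* physiological noise at cardiac (1–1.5 Hz), respiratory (0.2–0.5 Hz) and
  Mayer-wave (~0.1 Hz) frequencies, plus slow drift, a DC offset and white
  sensor noise;
* a balanced, randomly ordered trial sequence with a ~30 s inter-trial
  interval.

The evoked waveform is a canonical double-gamma hemodynamic response
function (HRF); the generator is a pure function of its configuration, so
identical configs (including the seed) give bit-identical recordings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .types import Event, Recording, TaskLabel

__all__ = ["SimConfig", "hrf_kernel", "generate_recording", "true_labels"]

N_CHANNELS = 20

# Evoked-response gains per (task, hemisphere-relation), in units of
# cfg.effect_amplitude.  Contralateral hand taps drive a strong positive HbO
# response; ipsilateral channels see a small spillover.  Foot taps produce a
# bilateral HbO decrease with an HbR increase.
_HBO_GAIN = {
    TaskLabel.RHT: {"left": 1.0, "right": 0.05},
    TaskLabel.LHT: {"left": 0.05, "right": 1.0},
    TaskLabel.FT: {"left": -0.8, "right": -0.8},
}
_HBR_RATIO = {TaskLabel.RHT: -0.35, TaskLabel.LHT: -0.35, TaskLabel.FT: -0.6}
# HbR = ratio × HbO-gain × HRF; negative ratio flips sign, so FT (negative
# HbO gain) yields a positive HbR response, and hand taps a negative one.


def _default_noise() -> dict[str, float]:
    return {"cardiac": 0.2, "respiration": 0.3, "mayer": 0.3, "drift": 0.5, "white": 0.1}


@dataclass
class SimConfig:
    """Simulation parameters; all randomness flows from ``seed``."""

    n_trials_per_class: int = 10
    sampling_rate: float = 10.0
    inter_trial_interval: float = 30.0
    iti_jitter: float = 5.0
    task_duration: float = 10.0
    hrf_peak_time: float = 6.0
    hrf_undershoot_ratio: float = 1.0 / 6.0
    effect_amplitude: float = 1.0
    noise_amplitudes: dict[str, float] = field(default_factory=_default_noise)
    cardiac_freq: float = 1.2
    respiration_freq: float = 0.3
    mayer_freq: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials_per_class < 1:
            raise ValueError("n_trials_per_class must be >= 1")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if any(v < 0 for v in self.noise_amplitudes.values()):
            raise ValueError("noise amplitudes must be non-negative")
        if not (1.0 <= self.cardiac_freq <= 1.5):
            raise ValueError("cardiac_freq must lie in the 1–1.5 Hz band")
        if not (0.2 <= self.respiration_freq <= 0.5):
            raise ValueError("respiration_freq must lie in the 0.2–0.5 Hz band")
        if not (0.05 <= self.mayer_freq <= 0.15):
            raise ValueError("mayer_freq must lie near 0.1 Hz (0.05–0.15)")


def hrf_kernel(
    time_grid: np.ndarray,
    peak_time: float = 6.0,
    undershoot_ratio: float = 1.0 / 6.0,
) -> np.ndarray:
    """Canonical double-gamma hemodynamic response sampled on ``time_grid``.

    The kernel is a positive gamma density peaking near ``peak_time`` minus
    ``undershoot_ratio`` times a later, wider gamma density (the post-stimulus
    undershoot), normalized so its maximum is 1.  It is exactly 0 at t = 0.

    Parameters
    ----------
    time_grid : increasing, non-negative sample times in seconds.
    peak_time : approximate time-to-peak of the positive lobe, seconds.
    undershoot_ratio : amplitude of the undershoot relative to the peak lobe;
        0 disables the undershoot.
    """
    t = np.asarray(time_grid, dtype=float)
    if t.size == 0:
        raise ValueError("time_grid must be non-empty")
    if np.any(t < 0):
        raise ValueError("time_grid must be non-negative")
    if t.size > 1 and np.any(np.diff(t) <= 0):
        raise ValueError("time_grid must be strictly increasing")

    # Gamma shape/scale chosen so the mode (shape-1)*scale sits at peak_time.
    scale = 1.0
    shape_main = peak_time / scale + 1.0
    shape_under = (peak_time + 10.0) / scale + 1.0
    kernel = stats.gamma.pdf(t, a=shape_main, scale=scale)
    if undershoot_ratio != 0.0:
        under = stats.gamma.pdf(t, a=shape_under, scale=scale)
        umax = stats.gamma.pdf((shape_under - 1.0) * scale, a=shape_under, scale=scale)
        kmax = stats.gamma.pdf((shape_main - 1.0) * scale, a=shape_main, scale=scale)
        kernel = kernel - undershoot_ratio * (kmax / umax) * under
    peak = np.max(np.abs(kernel))
    if peak > 0:
        kernel = kernel / np.max(kernel)
    return kernel


def _schedule_events(cfg: SimConfig, rng: np.random.Generator) -> list[Event]:
    labels = np.repeat(np.arange(3), cfg.n_trials_per_class)
    rng.shuffle(labels)
    events: list[Event] = []
    # Lead-in long enough for the -2 s epoch margin.
    t = 15.0
    for code in labels:
        events.append(Event(onset=float(t), label=TaskLabel(int(code)), duration=cfg.task_duration))
        jitter = rng.uniform(-cfg.iti_jitter, cfg.iti_jitter) if cfg.iti_jitter > 0 else 0.0
        t += cfg.inter_trial_interval + jitter
    return events


def generate_recording(cfg: SimConfig) -> Recording:
    """Simulate a 20-channel ΔHbO/ΔHbR recording under ``cfg``.

    Channels 0–9 are tagged left hemisphere, 10–19 right.  Raises a
    ``ValueError`` if the sampling rate would alias the cardiac component.
    """
    if cfg.sampling_rate < 2.0 * cfg.cardiac_freq:
        raise ValueError(
            f"sampling_rate {cfg.sampling_rate} Hz aliases cardiac noise at "
            f"{cfg.cardiac_freq} Hz (need >= {2 * cfg.cardiac_freq} Hz)"
        )
    rng = np.random.default_rng(cfg.seed)
    events = _schedule_events(cfg, rng)

    tail = 35.0  # room for the last epoch window plus HRF decay
    duration = events[-1].onset + tail
    n_samples = int(math.ceil(duration * cfg.sampling_rate))
    t = np.arange(n_samples) / cfg.sampling_rate
    sides = ["left"] * (N_CHANNELS // 2) + ["right"] * (N_CHANNELS // 2)

    hbo = np.zeros((N_CHANNELS, n_samples))
    hbr = np.zeros((N_CHANNELS, n_samples))

    # Task-evoked responses as sampled HRF kernels per trial (trials are
    # sparse).  Foot taps get a slower, broader kernel: the medial foot
    # representation reaches lateral optodes diluted and temporally smeared,
    # so the FT time course is not a mirror image of a hand-tap response.
    hrf_span = 30.0
    n_k = int(hrf_span * cfg.sampling_rate)
    grid = np.arange(n_k) / cfg.sampling_rate
    kernel_hand = hrf_kernel(grid, cfg.hrf_peak_time, cfg.hrf_undershoot_ratio)
    kernel_foot = hrf_kernel(grid, cfg.hrf_peak_time + 2.0, cfg.hrf_undershoot_ratio)
    for ev in events:
        kernel = kernel_foot if ev.label == TaskLabel.FT else kernel_hand
        i0 = int(round(ev.onset * cfg.sampling_rate))
        i1 = min(i0 + n_k, n_samples)
        seg = kernel[: i1 - i0]
        for ch in range(N_CHANNELS):
            g = _HBO_GAIN[ev.label][sides[ch]] * cfg.effect_amplitude
            hbo[ch, i0:i1] += g * seg
            hbr[ch, i0:i1] += _HBR_RATIO[ev.label] * g * seg

    amp = cfg.noise_amplitudes
    for ch in range(N_CHANNELS):
        for key, freq in (
            ("cardiac", cfg.cardiac_freq),
            ("respiration", cfg.respiration_freq),
            ("mayer", cfg.mayer_freq),
        ):
            a = amp.get(key, 0.0)
            if a > 0:
                phase_o = rng.uniform(0, 2 * np.pi)
                phase_r = rng.uniform(0, 2 * np.pi)
                hbo[ch] += a * np.sin(2 * np.pi * freq * t + phase_o)
                hbr[ch] += 0.5 * a * np.sin(2 * np.pi * freq * t + phase_r)
        a = amp.get("drift", 0.0)
        if a > 0:
            # DC offset plus a very slow (~0.005 Hz) baseline wander.
            dc_o, dc_r = rng.normal(0, a, size=2)
            ph = rng.uniform(0, 2 * np.pi)
            hbo[ch] += dc_o + a * np.sin(2 * np.pi * 0.005 * t + ph)
            hbr[ch] += dc_r + 0.5 * a * np.sin(2 * np.pi * 0.005 * t + ph)
        a = amp.get("white", 0.0)
        if a > 0:
            hbo[ch] += rng.normal(0, a, size=n_samples)
            hbr[ch] += rng.normal(0, a, size=n_samples)

    return Recording(
        hbo=hbo, hbr=hbr, sampling_rate=cfg.sampling_rate, events=events, channel_side=sides
    )


def true_labels(recording: Recording) -> list[TaskLabel]:
    """Ground-truth labels in event order."""
    if not recording.events:
        raise ValueError("recording has no events")
    return [ev.label for ev in recording.events]
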