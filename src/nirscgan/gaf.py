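"""Gramian angular summation field (GASF) encoding of epoch series.

A 1-D series is compressed to 28 points by piecewise aggregate
approximation (PAA), rescaled affinely to [−1, 1], lifted to polar
coordinates via φ_i = arccos(x̃_i), and turned into the symmetric Gram-like
matrix G_ij = cos(φ_i + φ_j) = x̃_i x̃_j − √(1−x̃_i²)·√(1−x̃_j²).  The matrix
is then mapped to pixel intensities in [0, 1] by (v+1)/2, giving the
28×28 grayscale images the generative and classifier networks consume.
"""

from __future__ import annotations

import logging

import numpy as np
from skimage.transform import resize

from .types import IMAGE_SIDE, Epoch, GASFImage, TaskLabel

__all__ = ["paa_downsample", "rescale_unit", "gasf", "to_image", "encode_epoch"]

logger = logging.getLogger(__name__)


def paa_downsample(series: np.ndarray, m: int) -> np.ndarray:
    """Piecewise aggregate approximation: means over m contiguous segments.

    Segment boundaries are ``round(len * k / m)``, so segments are exact
    when m divides the length and differ by at most one sample otherwise.
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    n = x.size
    if not (1 <= m <= n):
        raise ValueError(f"m must satisfy 1 <= m <= {n}, got {m}")
    if m == n:
        return x.copy()
    bounds = np.round(np.linspace(0, n, m + 1)).astype(int)
    return np.array([x[bounds[k]:bounds[k + 1]].mean() for k in range(m)])


def rescale_unit(series: np.ndarray) -> np.ndarray:
    """Affine map of a series onto [−1, 1] (min → −1, max → +1).

    A constant series has no scale; by convention it maps to all zeros
    (the midpoint), which is logged as a degenerate input.
    """
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("series must be non-empty")
    lo, hi = x.min(), x.max()
    if hi - lo == 0:
        logger.warning("DEGENERATE_SERIES constant input; rescaled to all-zero")
        return np.zeros_like(x)
    return 2.0 * (x - lo) / (hi - lo) - 1.0


def gasf(series: np.ndarray) -> np.ndarray:
    """Gramian angular summation field of a series already in [−1, 1].

    G_ij = cos(arccos x̃_i + arccos x̃_j); the diagonal is 2x̃_i² − 1 and every
    entry lies in [−1, 1].  Values outside [−1, 1] by more than 1e-12 are
    rejected; tiny excursions are clipped.
    """
    x = np.asarray(series, dtype=float)
    if np.any(np.abs(x) > 1.0 + 1e-12):
        raise ValueError("gasf input must lie in [-1, 1]")
    x = np.clip(x, -1.0, 1.0)
    root = np.sqrt(1.0 - x * x)
    return np.outer(x, x) - np.outer(root, root)


def to_image(matrix: np.ndarray, label: TaskLabel, provenance: str = "real") -> GASFImage:
    """Map a GASF matrix in [−1,1] to a 28×28 grayscale image in [0,1].

    Pixels are (v+1)/2 exactly when the matrix is already 28×28; other sizes
    are bilinearly resampled to 28×28 first, then clamped to [0, 1].
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"matrix must be square, got shape {m.shape}")
    if m.shape[0] != IMAGE_SIDE:
        m = resize(m, (IMAGE_SIDE, IMAGE_SIDE), order=1, mode="edge", anti_aliasing=False)
    pix = np.clip((m + 1.0) / 2.0, 0.0, 1.0)
    return GASFImage(pixels=pix, label=label, provenance=provenance)


def encode_epoch(
    epoch: Epoch,
    channel: int,
    chromophore: str = "hbo",
    *,
    series: np.ndarray | None = None,
) -> GASFImage:
    """Encode one epoch's selected series as a GASF image.

    Takes the post-onset portion (t ≥ 0; the pre-onset samples are baseline
    reference only), PAA-compresses it to 28 points, rescales to [−1, 1],
    computes the GASF and maps it to pixels.  ``series`` overrides the
    channel/chromophore selection (e.g. to encode a kernel-PCA component).
    """
    if series is None:
        if not (0 <= channel < epoch.n_channels):
            raise ValueError(f"channel {channel} out of range [0, {epoch.n_channels})")
        if chromophore not in ("hbo", "hbr"):
            raise ValueError("chromophore must be 'hbo' or 'hbr'")
        data = epoch.hbo if chromophore == "hbo" else epoch.hbr
        onset_idx = int(round(-epoch.t0_offset * epoch.sampling_rate))
        x = data[channel, onset_idx:]
    else:
        x = np.asarray(series, dtype=float)
    compressed = paa_downsample(x, IMAGE_SIDE)
    return to_image(gasf(rescale_unit(compressed)), epoch.label)
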