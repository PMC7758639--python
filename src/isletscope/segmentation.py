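"""Binary segmentation of the insulin (and CD45) channels.

Two interchangeable backends produce the binary mask consumed by the
quantification stages:

* a deterministic classical backend (optional Gaussian smoothing in physical
  units followed by a fixed or Otsu threshold), which is the pipeline's
  reference backend, and
* a compact trainable slice-wise encoder–decoder (:mod:`isletscope.segnet`),
  mirroring slice-by-slice semantic segmentation of the full stacks.

Otsu's threshold is computed on the exact 16-bit integer histogram: the level
maximizing between-class variance over all 65,536 candidate levels, ties
resolved toward the lowest level, which makes the choice fully deterministic.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .volio import ChannelVolume


def rescale_intensity(volume: ChannelVolume) -> ChannelVolume:
    """Affinely map intensities so min -> 0 and max -> 1.

    Raises on a constant volume, where the rescale is undefined.
    """
    data = volume.data.astype(np.float64)
    lo, hi = data.min(), data.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant volume (max == min)")
    return ChannelVolume((data - lo) / (hi - lo), volume.resolution, volume.channel)


def otsu_threshold(data: np.ndarray) -> int:
    """Otsu's threshold on integer data via the exact histogram.

    Returns the level t maximizing the between-class variance of the split
    ``{v <= t} / {v > t}`` over all 16-bit levels; ties take the lowest t.
    """
    flat = np.asarray(data).ravel()
    if flat.min() < 0 or flat.max() > 65535:
        raise ValueError("otsu_threshold expects 16-bit-range integer data")
    hist = np.bincount(flat.astype(np.int64), minlength=65536).astype(np.float64)
    total = hist.sum()
    levels = np.arange(65536, dtype=np.float64)
    w0 = np.cumsum(hist)
    mu0_sum = np.cumsum(hist * levels)
    mu_total = mu0_sum[-1]
    w1 = total - w0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = mu0_sum / w0
        mu1 = (mu_total - mu0_sum) / w1
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[~np.isfinite(var_between)] = -1.0
    return int(np.argmax(var_between))   # argmax takes the first (lowest) maximizer


def threshold_segment(
    channel: ChannelVolume,
    smooth_sigma_um: float = 0.0,
    method: str = "otsu",
    level: float | None = None,
) -> np.ndarray:
    """Binary mask from an insulin or CD45 channel.

    Smoothing, if requested, is applied in physical units: the Gaussian sigma
    in µm is converted per axis by the voxel resolution.  ``method="fixed"``
    thresholds at ``level``; ``method="otsu"`` picks the exact-histogram Otsu
    level.  The mask keeps voxels strictly above the threshold.
    """
    if channel.channel not in ("insulin", "cd45"):
        raise ValueError(f"threshold_segment expects insulin or cd45, got {channel.channel!r}")
    data = channel.data.astype(np.float64)
    if smooth_sigma_um and smooth_sigma_um > 0:
        sigma_vox = [smooth_sigma_um / r for r in channel.resolution]
        data = ndimage.gaussian_filter(data, sigma=sigma_vox)
    if method == "fixed":
        if level is None:
            raise ValueError("fixed thresholding requires an explicit level")
        t = float(level)
    elif method == "otsu":
        t = float(otsu_threshold(np.rint(data).astype(np.int64)))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return (data > t).astype(np.uint8)


def dice_coefficient(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); two empty masks count as identical (1)."""
    a = np.asarray(mask_a).astype(bool)
    b = np.asarray(mask_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)
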