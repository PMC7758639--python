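"""Ki67⁺ nucleus calling: background subtraction, peak seeding, seeded
watershed and size filtering, followed by attribution of calls to islets.

The stage order is fixed and each stage is deterministic:

1. slice-by-slice background subtraction by morphological opening with a
   disk element (removes smooth background, preserves nucleus-scale spots);
2. local-maximum seeding with a moving 5x5x3 (x, y, z) filter cube;
3. seeded watershed on the inverted intensity with a background intensity
   cutoff at 50 (on the background-subtracted scale);
4. removal of regions smaller than 4 or bigger than 100 voxels (4 and 100
   themselves survive);
5. attribution of each surviving call to the islet whose label contains its
   peak voxel (peak-membership, not region overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import ndimage
from skimage.morphology import disk, opening
from skimage.segmentation import watershed

from .isletquant import IsletRecord
from .volio import ChannelVolume, Ki67Params


@dataclass(frozen=True)
class SpotCall:
    """One retained Ki67⁺ nucleus candidate."""

    peak: tuple[int, int, int]    # (z, y, x) seed voxel
    region_voxels: int
    region_label: int
    islet_id: int = 0             # 0 = outside every islet


def open_background_subtract(channel: ChannelVolume, disk_radius: int = 4) -> ChannelVolume:
    """Slice-by-slice white-tophat: input minus its morphological opening.

    The opening with a disk of the given radius estimates the smooth local
    background of each z-slice; subtracting it leaves nucleus-scale peaks on
    a near-zero floor.  Output is nonnegative by construction.
    """
    if disk_radius < 1:
        raise ValueError("disk_radius must be >= 1")
    data = channel.data
    if 2 * disk_radius + 1 > min(data.shape[1], data.shape[2]):
        raise ValueError(
            f"disk radius {disk_radius} exceeds the slice extent {data.shape[1:]}"
        )
    footprint = disk(disk_radius)
    out = np.empty_like(data)
    for z in range(data.shape[0]):
        out[z] = data[z] - opening(data[z], footprint)
    return ChannelVolume(out, channel.resolution, channel.channel)


def find_peak_seeds(volume: np.ndarray, cube_zyx: tuple[int, int, int] = (3, 5, 5)) -> np.ndarray:
    """Local-maximum seeds from a moving filter cube.

    A voxel is a seed iff its value is positive and equals the maximum of its
    cube neighborhood.  A connected plateau of tied maxima yields a single
    seed at its lexicographically smallest ``(z, y, x)`` voxel.

    Returns an ``(n, 3)`` integer array of seed coordinates in raster order.
    """
    volume = np.asarray(volume)
    if any(c % 2 == 0 or c < 1 for c in cube_zyx):
        raise ValueError("cube dimensions must be odd positive integers")
    if any(c > s for c, s in zip(cube_zyx, volume.shape)):
        raise ValueError(f"cube {cube_zyx} larger than the volume {volume.shape}")
    local_max = ndimage.maximum_filter(volume, size=cube_zyx, mode="constant", cval=0)
    candidates = (volume == local_max) & (volume > 0)
    if not candidates.any():
        return np.empty((0, 3), dtype=np.int64)
    # collapse connected plateaus (26-connectivity) to their first voxel
    labels, n = ndimage.label(candidates, structure=np.ones((3, 3, 3), bool))
    coords = np.argwhere(labels > 0)   # argwhere is raster (lexicographic) order
    lab = labels[tuple(coords.T)]
    _, first = np.unique(lab, return_index=True)
    return coords[np.sort(first)]


def watershed_regions(
    volume: np.ndarray,
    seeds: np.ndarray,
    background_cutoff: float = 50.0,
) -> np.ndarray:
    """Seeded watershed on the inverted intensity.

    Voxels with intensity <= cutoff are background (label 0); each region
    grows from exactly one seed.  Seeds sitting at or below the cutoff are
    dropped with a warning rather than an error.
    """
    volume = np.asarray(volume)
    seeds = np.asarray(seeds, dtype=np.int64).reshape(-1, 3)
    if len(seeds) == 0:
        raise ValueError("watershed requires at least one seed")
    if background_cutoff < 0:
        raise ValueError("background cutoff must be >= 0")
    vals = volume[tuple(seeds.T)]
    keep = vals > background_cutoff
    if not np.all(keep):
        warnings.warn(
            f"dropping {int((~keep).sum())} seed(s) at intensity <= "
            f"{background_cutoff}", stacklevel=2,
        )
    seeds = seeds[keep]
    markers = np.zeros(volume.shape, dtype=np.int32)
    for i, (z, y, x) in enumerate(seeds, start=1):
        markers[z, y, x] = i
    mask = volume > background_cutoff
    return watershed(-volume.astype(np.float64), markers=markers, mask=mask,
                     connectivity=np.ones((3, 3, 3), bool)).astype(np.int32)


def filter_regions(
    labels: np.ndarray,
    seeds: np.ndarray | None = None,
    region_min: int = 4,
    region_max: int = 100,
) -> list[SpotCall]:
    """Keep regions with ``region_min <= voxels <= region_max`` (inclusive).

    ``seeds`` (the watershed markers, in label order) provide the peak voxel
    of each region; when omitted, the region's first raster voxel stands in.
    """
    labels = np.asarray(labels)
    n = int(labels.max(initial=0))
    if n == 0:
        return []
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    calls = []
    for lab in range(1, n + 1):
        c = int(counts[lab])
        if c == 0 or not region_min <= c <= region_max:
            continue
        if seeds is not None and lab <= len(seeds):
            peak = tuple(int(v) for v in np.asarray(seeds)[lab - 1])
        else:
            peak = tuple(int(v) for v in np.argwhere(labels == lab)[0])
        calls.append(SpotCall(peak=peak, region_voxels=c, region_label=lab))
    return calls


def count_spots_per_islet(
    calls: Sequence[SpotCall],
    islet_labels: np.ndarray,
) -> tuple[list[SpotCall], dict[int, int]]:
    """Attribute calls to islets by peak-voxel membership.

    Returns the calls annotated with their ``islet_id`` (0 when the peak lies
    outside every islet — such calls are excluded from islet counts) and a
    per-islet count for every islet label present in the volume.
    """
    islet_labels = np.asarray(islet_labels)
    counts: dict[int, int] = {int(i): 0 for i in np.unique(islet_labels) if i > 0}
    annotated = []
    for call in calls:
        z, y, x = call.peak
        if not (0 <= z < islet_labels.shape[0]
                and 0 <= y < islet_labels.shape[1]
                and 0 <= x < islet_labels.shape[2]):
            raise ValueError(f"peak {call.peak} outside the islet label volume "
                             f"{islet_labels.shape}")
        islet_id = int(islet_labels[z, y, x])
        annotated.append(SpotCall(call.peak, call.region_voxels, call.region_label, islet_id))
        if islet_id > 0:
            counts[islet_id] += 1
    return annotated, counts


def attach_counts_to_records(records: Sequence[IsletRecord], counts: dict[int, int]) -> list[IsletRecord]:
    """Fill ki67_count / ki67_positive on islet records from per-islet counts."""
    out = []
    for r in records:
        c = int(counts.get(r.islet_id, 0))
        r.ki67_count = c
        r.ki67_positive = c >= 1
        out.append(r)
    return out


def call_ki67(
    channel: ChannelVolume,
    islet_labels: np.ndarray,
    params: Ki67Params | None = None,
) -> tuple[list[SpotCall], dict[int, int]]:
    """Run the full nucleus-calling chain on a Ki67 channel."""
    params = params or Ki67Params()
    params.validate()
    if channel.data.shape != np.asarray(islet_labels).shape:
        raise ValueError("Ki67 channel and islet label volume shapes differ")
    subtracted = open_background_subtract(channel, params.opening_radius)
    seeds = find_peak_seeds(subtracted.data, params.peak_cube_zyx())
    if len(seeds) == 0:
        return [], {int(i): 0 for i in np.unique(islet_labels) if i > 0}
    vals = subtracted.data[tuple(seeds.T)]
    seeds = seeds[vals > params.watershed_cutoff]
    if len(seeds) == 0:
        return [], {int(i): 0 for i in np.unique(islet_labels) if i > 0}
    labels = watershed_regions(subtracted.data, seeds, params.watershed_cutoff)
    calls = filter_regions(labels, seeds, params.region_min, params.region_max)
    return count_spots_per_islet(calls, islet_labels)
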