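"""Islet labeling, physical volumes, size binning and per-sample summaries.

A binary insulin mask is decomposed into 3D connected components (one label
per islet), each component gets a physical volume (voxel count x voxel
volume), candidates below the low-size cutoff of 25 x 1000 µm³ are discarded
as likely nonspecific signal, and the survivors are assigned to four size
categories:

    small       [25, 170) x 1000 µm³
    medium      [170, 1100) x 1000 µm³
    large       [1100, 7500) x 1000 µm³
    very_large  [7500, 50000) x 1000 µm³

Intervals are half-open on the right; volumes at or above the top edge are by
default kept in ``very_large`` (the top edge reflects the largest islet
observed, not an exclusion rule), with a strict mode to drop them instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import ndimage

from .volio import DEFAULT_BIN_EDGES

BIN_NAMES = ("small", "medium", "large", "very_large")

_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3}


@dataclass(frozen=True)
class SizeBinScheme:
    """Contiguous half-open islet size intervals in units of 1000 µm³."""

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    names: tuple[str, ...] = BIN_NAMES
    strict_top: bool = False

    def __post_init__(self):
        edges = tuple(float(e) for e in self.edges)
        if len(edges) != len(self.names) + 1:
            raise ValueError("need exactly one more edge than bin names")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        object.__setattr__(self, "edges", edges)

    @property
    def cutoff(self) -> float:
        return self.edges[0]

    def assign(self, volume_1000um3: float) -> str | None:
        """Bin name for a volume, or ``None`` if below cutoff (or above the
        top edge in strict mode)."""
        v = float(volume_1000um3)
        if v < self.cutoff:
            return None
        if v >= self.edges[-1]:
            return None if self.strict_top else self.names[-1]
        idx = int(np.searchsorted(self.edges, v, side="right")) - 1
        return self.names[idx]


@dataclass
class IsletRecord:
    """One segmented islet and everything measured on it."""

    islet_id: int
    voxels: int
    volume_1000um3: float
    centroid: tuple[float, float, float]          # (z, y, x) voxel coords
    bin: str | None = None
    ki67_count: int | None = None
    ki67_positive: bool | None = None
    cd45_fraction: float | None = None
    inflamed: bool | None = None
    sample_id: str = ""

    def __post_init__(self):
        if self.islet_id < 1:
            raise ValueError("islet_id must be a positive integer")
        if self.voxels < 1:
            raise ValueError("voxels must be >= 1")
        if self.cd45_fraction is not None and not 0.0 <= self.cd45_fraction <= 1.0:
            raise ValueError("cd45_fraction must lie in [0, 1]")


@dataclass
class PancreasResult:
    """Per-sample aggregates over binned islet records."""

    sample_id: str
    total_islets: int
    total_beta_volume_mm3: float
    bin_counts: dict[str, int]
    bin_volumes_mm3: dict[str, float]
    bin_ki67_positive: dict[str, int] | None = None
    total_ki67_cells: int | None = None
    bin_inflamed: dict[str, int] | None = None

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "total_islets": self.total_islets,
            "total_beta_volume_mm3": self.total_beta_volume_mm3,
            "bin_counts": self.bin_counts,
            "bin_volumes_mm3": self.bin_volumes_mm3,
            "bin_ki67_positive": self.bin_ki67_positive,
            "total_ki67_cells": self.total_ki67_cells,
            "bin_inflamed": self.bin_inflamed,
        }


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3x3x3 structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = _CONNECTIVITY_RANK[connectivity]
    except KeyError:
        raise ValueError("connectivity must be 6, 18 or 26") from None
    return ndimage.generate_binary_structure(3, rank)


def label_components(mask: np.ndarray, connectivity: int = 26) -> tuple[np.ndarray, int]:
    """Label connected components of a binary mask.

    Labels run 1..K with background 0, assigned in raster-scan order of each
    component's first (minimum ``(z,y,x)``) voxel, which makes labeling
    deterministic and independent of how the mask was produced.
    """
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("mask must be binary (0/1 or bool)")
    labels, count = ndimage.label(mask.astype(bool), structure=connectivity_structure(connectivity))
    return labels.astype(np.int32), int(count)


def voxel_volume_um3(resolution: Sequence[float]) -> float:
    """Physical volume of one voxel in µm³ given (dz, dy, dx) in µm."""
    dz, dy, dx = (float(r) for r in resolution)
    if dz <= 0 or dy <= 0 or dx <= 0:
        raise ValueError("resolution must be strictly positive")
    return dz * dy * dx


def records_from_labels(
    labels: np.ndarray,
    resolution: Sequence[float],
    sample_id: str = "",
) -> list[IsletRecord]:
    """Geometry-only islet records (id, voxel count, volume, centroid) from a
    label volume.  Ki67/CD45 fields are left unset for later stages."""
    labels = np.asarray(labels)
    n = int(labels.max(initial=0))
    if n == 0:
        return []
    vv = voxel_volume_um3(resolution)
    counts = np.bincount(labels.ravel(), minlength=n + 1)
    ids = [i for i in range(1, n + 1) if counts[i] > 0]
    centroids = ndimage.center_of_mass(np.ones_like(labels, dtype=np.uint8), labels, ids)
    return [
        IsletRecord(
            islet_id=int(i),
            voxels=int(counts[i]),
            volume_1000um3=counts[i] * vv / 1000.0,
            centroid=tuple(float(c) for c in cen),
            sample_id=sample_id,
        )
        for i, cen in zip(ids, centroids)
    ]


def apply_cutoff_and_bin(
    records: Sequence[IsletRecord],
    scheme: SizeBinScheme | None = None,
) -> list[IsletRecord]:
    """Drop records below the size cutoff and assign each survivor its bin."""
    scheme = scheme or SizeBinScheme()
    out = []
    for r in records:
        b = scheme.assign(r.volume_1000um3)
        if b is not None:
            out.append(replace(r, bin=b))
    return out


def summarize_sample(
    records: Sequence[IsletRecord],
    sample_id: str,
    bin_names: Sequence[str] = BIN_NAMES,
) -> PancreasResult:
    """Aggregate binned records into a :class:`PancreasResult`.

    Beta-cell volume is reported in mm³ (1 mm³ = 10⁶ x 1000 µm³... precisely,
    1 mm³ = 1e9 µm³ = 1e6 units of 1000 µm³).
    """
    for r in records:
        if r.bin is None:
            raise ValueError(f"record {r.islet_id} is unbinned; run apply_cutoff_and_bin first")

    to_mm3 = 1e-6  # 1000 µm³ -> mm³
    counts = {b: 0 for b in bin_names}
    volumes = {b: 0.0 for b in bin_names}
    ki67_pos = {b: 0 for b in bin_names}
    inflamed = {b: 0 for b in bin_names}
    any_ki67 = any(r.ki67_count is not None for r in records)
    any_cd45 = any(r.cd45_fraction is not None for r in records)
    total_ki67 = 0
    for r in records:
        counts[r.bin] += 1
        volumes[r.bin] += r.volume_1000um3 * to_mm3
        if r.ki67_count is not None:
            total_ki67 += r.ki67_count
            if r.ki67_positive:
                ki67_pos[r.bin] += 1
        if r.inflamed:
            inflamed[r.bin] += 1

    return PancreasResult(
        sample_id=sample_id,
        total_islets=len(records),
        total_beta_volume_mm3=sum(volumes.values()),
        bin_counts=counts,
        bin_volumes_mm3=volumes,
        bin_ki67_positive=ki67_pos if any_ki67 else None,
        total_ki67_cells=total_ki67 if any_ki67 else None,
        bin_inflamed=inflamed if any_cd45 else None,
    )
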