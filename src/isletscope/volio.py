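"""Volume and table I/O, acquisition geometry and pipeline configuration.

The universal image currency is :class:`ChannelVolume`: a 3D intensity grid in
``(z, y, x)`` axis order together with its physical voxel resolution in µm and
the channel identity (insulin, ki67 or cd45).  Default geometry follows whole-
pancreas light-sheet acquisition: 4.8 µm in-plane sampling and a 10 µm z-step,
so one voxel is 4.8 x 4.8 x 10 = 230.4 µm³.

Volume depth uses the z sampling pitch (10 µm), not the optical z-resolution
(3.78 µm): volumes are sums over sampled voxels, and the sampling pitch defines
a voxel's physical extent.  Both are exposed through configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("isletscope")
if not logger.handlers:  # structured parameter log to stderr by default
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(name)s %(levelname)s %(message)s"))
    logger.addHandler(_h)
    logger.setLevel(logging.INFO)

#: µm per voxel along (z, y, x) for the reference acquisition geometry.
DEFAULT_RESOLUTION = (10.0, 4.8, 4.8)

CHANNELS = ("insulin", "ki67", "cd45")

#: Size-bin edges in units of 1000 µm³ (small/medium/large/very_large).
DEFAULT_BIN_EDGES = (25.0, 170.0, 1100.0, 7500.0, 50000.0)


class VolumeError(ValueError):
    """Raised for malformed volumes, resolutions or channel metadata."""


@dataclass(frozen=True)
class ChannelVolume:
    """A 3D intensity volume with physical voxel resolution.

    Parameters
    ----------
    data
        3D array, axis order ``(z, y, x)``, nonnegative intensities within the
        16-bit range.
    resolution
        ``(dz, dy, dx)`` in µm per voxel, all strictly positive.
    channel
        One of ``{"insulin", "ki67", "cd45"}``.
    """

    data: np.ndarray
    resolution: tuple[float, float, float]
    channel: str

    def __post_init__(self):
        data = np.asarray(self.data)
        if data.ndim != 3 or min(data.shape) < 1:
            raise VolumeError(f"expected a 3D (z,y,x) volume, got shape {data.shape}")
        res = tuple(float(r) for r in self.resolution)
        if len(res) != 3 or any(r <= 0 for r in res):
            raise VolumeError(f"resolution must be three positive µm values, got {self.resolution}")
        if data.size and (data.min() < 0 or data.max() > 65535):
            raise VolumeError("intensities must lie in the 16-bit range [0, 65535]")
        if self.channel not in CHANNELS:
            raise VolumeError(f"channel must be one of {CHANNELS}, got {self.channel!r}")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "resolution", res)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.resolution
        return dz * dy * dx


@dataclass
class Ki67Params:
    """Ki67 nucleus-calling constants.

    The peak-search cube is given in acquisition ``(x, y, z)`` order as in the
    published protocol (5, 5, 3); conversion to the internal ``(z, y, x)`` axis
    order happens here, once.
    """

    opening_radius: int = 4            # voxels; background-subtraction disk
    peak_cube: tuple[int, int, int] = (5, 5, 3)   # (x, y, z) voxels
    watershed_cutoff: float = 50.0     # on background-subtracted intensities
    region_min: int = 4                # voxels, inclusive
    region_max: int = 100              # voxels, inclusive

    def peak_cube_zyx(self) -> tuple[int, int, int]:
        cx, cy, cz = self.peak_cube
        return (cz, cy, cx)

    def validate(self) -> None:
        if self.opening_radius < 1:
            raise ValueError("ki67.opening_radius must be >= 1")
        if any(c < 1 or c % 2 == 0 for c in self.peak_cube):
            raise ValueError("ki67.peak_cube dims must be odd positive integers")
        if self.region_min > self.region_max:
            raise ValueError("ki67.region_min must be <= ki67.region_max")
        if self.watershed_cutoff < 0:
            raise ValueError("ki67.watershed_cutoff must be >= 0")


@dataclass
class SegmentationParams:
    """Settings for the insulin / CD45 segmentation backend."""

    backend: str = "threshold"         # "threshold" (deterministic) or "trained"
    method: str = "otsu"               # for the threshold backend: "otsu" | "fixed"
    level: float | None = None         # required when method == "fixed"
    smooth_sigma_um: float = 0.0       # Gaussian pre-smoothing in physical units
    model_path: str | None = None      # for the trained backend

    def validate(self) -> None:
        if self.backend not in ("threshold", "trained"):
            raise ValueError(f"unknown segmentation backend {self.backend!r}")
        if self.method not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold method {self.method!r}")
        if self.smooth_sigma_um < 0:
            raise ValueError("segmentation.smooth_sigma_um must be >= 0")


@dataclass
class PipelineParams:
    """Every numeric constant of the quantification pipeline, with the
    published defaults.

    ``size_cutoff_1000um3`` removes islet candidates below 25 x 1000 µm³
    (false-positive suppression); ``bin_edges_1000um3`` define the four size
    categories small/medium/large/very_large; ``inflammation_threshold`` is the
    5% CD45 volume fraction defining an inflamed islet.
    """

    size_cutoff_1000um3: float = 25.0
    bin_edges_1000um3: tuple[float, ...] = DEFAULT_BIN_EDGES
    ki67: Ki67Params = field(default_factory=Ki67Params)
    inflammation_threshold: float = 0.05
    connectivity: int = 26
    resolution: tuple[float, float, float] = DEFAULT_RESOLUTION
    strict_top_bin: bool = False       # drop volumes >= top edge instead of keeping
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    seed: int = 0

    def validate(self) -> None:
        edges = tuple(float(e) for e in self.bin_edges_1000um3)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin_edges_1000um3 must be strictly increasing")
        if self.size_cutoff_1000um3 != edges[0]:
            raise ValueError(
                f"size_cutoff_1000um3 ({self.size_cutoff_1000um3}) must equal the "
                f"first bin edge ({edges[0]})"
            )
        if not 0.0 <= self.inflammation_threshold <= 1.0:
            raise ValueError("inflammation_threshold must lie in [0, 1]")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")
        if any(r <= 0 for r in self.resolution):
            raise ValueError("resolution must be strictly positive")
        self.ki67.validate()
        self.segmentation.validate()
        self.bin_edges_1000um3 = edges

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _update_dataclass(obj, values: dict, prefix: str):
    known = {f.name for f in dataclasses.fields(obj)}
    for key, val in values.items():
        if key not in known:
            raise ValueError(f"unknown configuration key '{prefix}{key}'")
        current = getattr(obj, key)
        if dataclasses.is_dataclass(current) and isinstance(val, dict):
            _update_dataclass(current, val, prefix=f"{prefix}{key}.")
        else:
            if isinstance(current, tuple) and isinstance(val, (list, tuple)):
                val = tuple(val)
            setattr(obj, key, val)


def load_params(path: str | Path | None = None, overrides: dict | None = None) -> PipelineParams:
    """Load :class:`PipelineParams` from a YAML/JSON config file.

    Unspecified fields take the published defaults.  Unknown keys raise (no
    silent ignoring); invariant violations raise naming the offending field.
    The full effective configuration is echoed to the log.
    """
    params = PipelineParams()
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config {path} must contain a mapping")
    if overrides:
        data = {**data, **overrides}
    _update_dataclass(params, data, prefix="")
    params.validate()
    logger.info("effective parameters: %s", json.dumps(params.to_dict(), default=list))
    return params


# ---------------------------------------------------------------------------
# Volume I/O
# ---------------------------------------------------------------------------

def read_volume(
    paths: str | Path | Sequence[str | Path],
    resolution: tuple[float, float, float] = DEFAULT_RESOLUTION,
    channel: str = "insulin",
) -> ChannelVolume:
    """Read a multi-page TIFF, or a series of single-slice TIFFs stacked in
    filename-sorted z order, into a :class:`ChannelVolume`.  Dtype preserved.
    """
    if isinstance(paths, (str, Path)):
        path = Path(paths)
        if not path.exists():
            raise FileNotFoundError(f"no such volume: {path}")
        data = tifffile.imread(path)
        if data.ndim == 2:
            data = data[None]
        return ChannelVolume(data, resolution, channel)

    files = [Path(p) for p in paths]
    if not files:
        raise ValueError("empty file list: at least one slice is required")
    files.sort(key=lambda p: p.name)
    slices = []
    shape = None
    for f in files:
        if not f.exists():
            raise FileNotFoundError(f"no such slice: {f}")
        s = tifffile.imread(f)
        if s.ndim != 2:
            raise VolumeError(f"slice {f} is not 2D (shape {s.shape})")
        if shape is None:
            shape = s.shape
        elif s.shape != shape:
            raise VolumeError(f"slice {f} has shape {s.shape}, expected {shape}")
        slices.append(s)
    return ChannelVolume(np.stack(slices), resolution, channel)


def write_volume(volume: ChannelVolume | np.ndarray, path: str | Path) -> None:
    """Write a volume as a multi-page TIFF (intensities or integer labels)."""
    data = volume.data if isinstance(volume, ChannelVolume) else np.asarray(volume)
    tifffile.imwrite(Path(path), data, photometric="minisblack")


def write_label_volume(labels: np.ndarray, path: str | Path) -> None:
    """Write a component label volume as 32-bit integer multi-page TIFF."""
    tifffile.imwrite(Path(path), np.asarray(labels, dtype=np.int32),
                     photometric="minisblack")


# ---------------------------------------------------------------------------
# Islet table I/O
# ---------------------------------------------------------------------------

ISLET_TABLE_COLUMNS = [
    "sample_id", "islet_id", "voxels", "volume_1000um3", "bin",
    "cz", "cy", "cx", "ki67_count", "ki67_positive", "cd45_fraction", "inflamed",
]


def write_islet_table(records, path: str | Path, sample_id: str = "") -> None:
    """Write islet records as CSV with a fixed header.

    Volumes are serialized at full float precision (repr round-trip), so
    re-binning after a round trip is unchanged.  Optional fields of stages not
    run (Ki67, CD45) are written as empty cells, not zeros.
    """
    rows = []
    for r in records:
        cz, cy, cx = r.centroid
        rows.append({
            "sample_id": r.sample_id if getattr(r, "sample_id", None) else sample_id,
            "islet_id": r.islet_id,
            "voxels": r.voxels,
            "volume_1000um3": np.float64(r.volume_1000um3),
            "bin": r.bin if r.bin is not None else "",
            "cz": cz, "cy": cy, "cx": cx,
            "ki67_count": "" if r.ki67_count is None else r.ki67_count,
            "ki67_positive": "" if r.ki67_positive is None else r.ki67_positive,
            "cd45_fraction": "" if r.cd45_fraction is None else np.float64(r.cd45_fraction),
            "inflamed": "" if r.inflamed is None else r.inflamed,
        })
    df = pd.DataFrame(rows, columns=ISLET_TABLE_COLUMNS)
    df.to_csv(Path(path), index=False, float_format="%.17g")


def read_islet_table(path: str | Path):
    """Read an islet CSV back into a list of IsletRecord."""
    from .isletquant import IsletRecord  # local import to avoid a cycle

    df = pd.read_csv(Path(path))
    missing = [c for c in ISLET_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"islet table {path} is missing columns {missing}")

    def _opt(v, cast):
        if pd.isna(v) or v == "":
            return None
        return cast(v)

    records = []
    for row in df.itertuples(index=False):
        records.append(IsletRecord(
            islet_id=int(row.islet_id),
            voxels=int(row.voxels),
            volume_1000um3=float(row.volume_1000um3),
            bin=_opt(row.bin, str),
            centroid=(float(row.cz), float(row.cy), float(row.cx)),
            ki67_count=_opt(row.ki67_count, lambda v: int(float(v))),
            ki67_positive=_opt(row.ki67_positive, lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v) == "True"),
            cd45_fraction=_opt(row.cd45_fraction, float),
            inflamed=_opt(row.inflamed, lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v) == "True"),
            sample_id=str(row.sample_id) if not pd.isna(row.sample_id) else "",
        ))
    return records
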