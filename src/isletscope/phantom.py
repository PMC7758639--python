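"""Synthetic 3D pancreas phantoms with exact ground truth.

A phantom emulates a cleared whole-pancreas light-sheet acquisition at
4.8 µm in-plane / 10 µm z-step: a 16-bit insulin channel containing
non-overlapping axis-aligned ellipsoidal islets spanning the four size
categories, a Ki67 channel with sparse bright Gaussian nuclei inside islets,
and a CD45 channel with leukocyte signal concentrated in a peripheral shell
of each islet plus interior speckle, scaled by a per-islet infiltration
fraction.  Every planted object is recorded in a :class:`PhantomTruth`, so
each downstream stage can be validated against exact ground truth.

Geometry is rasterized at voxel centers; the recorded voxel counts are the
rasterization counts on the actual grid, so recovery checks can be exact
rather than approximate.  Identical seeds give bit-identical phantoms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .isletquant import IsletRecord
from .volio import DEFAULT_RESOLUTION, ChannelVolume, write_volume


class PlacementError(RuntimeError):
    """Raised when non-overlapping islet placement fails (density too high)."""


@dataclass
class PhantomSpec:
    """Parameters of a synthetic pancreas volume.

    ``size_model`` is a log-normal on the islet equivalent-sphere radius
    (median in µm, sd of log radius); the default (40 µm, 0.6) spans all four
    size categories from the 25 x 1000 µm³ cutoff up to the very-large bin.
    ``nuclei_per_islet_model`` is a Poisson rate per µm³ of islet volume.
    ``infiltration_model`` is a Beta law on the per-islet CD45 volume
    fraction plus the thickness of the peripheral leukocyte shell.
    """

    shape: tuple[int, int, int] = (128, 256, 256)          # (z, y, x) voxels
    resolution: tuple[float, float, float] = DEFAULT_RESOLUTION  # µm per voxel
    n_islets: int = 50
    size_model: tuple[float, float] = (40.0, 0.6)          # (median radius µm, log-sd)
    stratify_bins: bool = False    # cycle islet volumes across the four bins
    islet_intensity: float = 20000.0
    nuclei_per_islet_model: float = 1.5e-5                 # nuclei per µm³
    nucleus_radius: float = 14.0         # µm, apparent (PSF-blurred) spot radius
    # chosen so the published watershed cutoff (50, on background-subtracted
    # intensities) falls between the noise floor left by the opening and the
    # nucleus peak, and so rendered spots fall inside the 4..100 voxel filter
    nucleus_intensity: float = 120.0
    nucleus_min_separation_vox: float = 6.0                # between any two centers
    infiltration_model: tuple[float, float] = (2.0, 8.0)   # Beta(a, b) on [0,1]
    shell_thickness_um: float = 15.0
    cd45_intensity: float = 15000.0
    background_level: float = 100.0
    noise_sd: float = 0.0
    poisson_noise: bool = False
    aspect_range: tuple[float, float] = (0.7, 1.4)
    min_gap_um: float = 25.0       # guaranteed clearance between islet surfaces
    max_retries: int = 500
    seed: int = 0

    def validate(self) -> None:
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError("shape must be three positive voxel counts")
        if any(r <= 0 for r in self.resolution):
            raise ValueError("resolution must be strictly positive")
        if self.n_islets < 0:
            raise ValueError("n_islets must be >= 0")
        for name in ("islet_intensity", "nucleus_intensity", "cd45_intensity", "background_level"):
            v = getattr(self, name)
            if not 0 <= v <= 65535:
                raise ValueError(f"{name} must lie in [0, 65535]")
        if self.nucleus_radius >= self.size_model[0]:
            raise ValueError("nucleus radius must be smaller than the median islet radius")
        a, b = self.infiltration_model
        if a <= 0 or b <= 0:
            raise ValueError("infiltration Beta parameters must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class IsletTruth:
    islet_id: int
    center_vox: tuple[float, float, float]   # (z, y, x), continuous voxel coords
    semi_axes_um: tuple[float, float, float]  # (az, ay, ax)
    voxels: int


@dataclass
class PhantomTruth:
    """Exact ground truth of one phantom volume."""

    islets: list[IsletTruth]
    nuclei: list[tuple[int, tuple[int, int, int]]]   # (islet_id, (z,y,x) voxel)
    infiltration: dict[int, int]                     # islet_id -> infiltrated voxels
    resolution: tuple[float, float, float]
    seed: int

    def nuclei_count(self, islet_id: int) -> int:
        return sum(1 for i, _ in self.nuclei if i == islet_id)


# volume (units of 1000 µm³) -> equivalent-sphere radius in µm
def _radius_from_volume_1000um3(v: float) -> float:
    return (3.0 * v * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)


_BIN_EDGES = (25.0, 170.0, 1100.0, 7500.0, 50000.0)


def _sample_radii(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    if spec.stratify_bins:
        # cycle islets through the four size categories with a small-heavy
        # mix (real pancreata are dominated by small and medium islets, and
        # very large islets could not physically pack at equal proportions),
        # uniform in log-volume inside each bin; the top bin is capped well
        # below its upper edge so very large islets still fit the volume
        caps = [170.0, 1100.0, 7500.0, 20000.0]
        pattern = [0, 1, 0, 2, 1, 0, 1, 3]      # per 8: 3 small, 3 medium, 1 large, 1 very large
        radii = []
        for i in range(spec.n_islets):
            b = pattern[i % len(pattern)]
            lo, hi = _BIN_EDGES[b], caps[b]
            v = np.exp(rng.uniform(np.log(lo * 1.05), np.log(hi * 0.95)))
            radii.append(_radius_from_volume_1000um3(v))
        return np.array(radii)
    median, log_sd = spec.size_model
    return median * np.exp(rng.normal(0.0, log_sd, size=spec.n_islets))


def _rasterize_ellipsoid(shape, resolution, center_vox, semi_axes_um):
    """Voxel-center rasterization; returns (slices, local boolean mask)."""
    dz, dy, dx = resolution
    cz, cy, cx = center_vox
    az, ay, ax = semi_axes_um
    # bounding box in voxel indices
    z0 = max(int(np.floor(cz - az / dz)) - 1, 0)
    z1 = min(int(np.ceil(cz + az / dz)) + 2, shape[0])
    y0 = max(int(np.floor(cy - ay / dy)) - 1, 0)
    y1 = min(int(np.ceil(cy + ay / dy)) + 2, shape[1])
    x0 = max(int(np.floor(cx - ax / dx)) - 1, 0)
    x1 = min(int(np.ceil(cx + ax / dx)) + 2, shape[2])
    zz = (np.arange(z0, z1) - cz) * dz / az
    yy = (np.arange(y0, y1) - cy) * dy / ay
    xx = (np.arange(x0, x1) - cx) * dx / ax
    m = (zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2) <= 1.0
    return (slice(z0, z1), slice(y0, y1), slice(x0, x1)), m


def generate_phantom(spec: PhantomSpec):
    """Generate the three channels and the ground truth of one phantom.

    Returns ``(insulin, ki67, cd45, truth)`` where the channels are
    :class:`ChannelVolume` and ``truth`` a :class:`PhantomTruth`.  Placement
    uses rejection sampling with a guaranteed surface-to-surface clearance;
    if a non-overlapping configuration cannot be found the error names the
    attempted islet density.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    dz, dy, dx = spec.resolution
    shape = tuple(int(s) for s in spec.shape)

    insulin = np.full(shape, spec.background_level, dtype=np.float64)
    ki67 = np.full(shape, spec.background_level, dtype=np.float64)
    cd45 = np.full(shape, spec.background_level, dtype=np.float64)
    islet_mask_labels = np.zeros(shape, dtype=np.int32)

    radii = _sample_radii(spec, rng)
    lo, hi = spec.aspect_range

    placed: list[tuple[np.ndarray, float]] = []   # (center µm, bounding radius µm)
    islets: list[IsletTruth] = []
    bboxes: dict[int, tuple] = {}
    for i, r in enumerate(radii, start=1):
        ratios = rng.uniform(lo, hi, size=3)
        ratios /= ratios.prod() ** (1.0 / 3.0)    # preserve equivalent radius
        semi = r * ratios                          # (az, ay, ax) µm
        bound = float(semi.max())
        extent_um = np.array([shape[0] * dz, shape[1] * dy, shape[2] * dx])
        margin = semi + np.array([dz, dy, dx])
        if np.any(extent_um - 2 * margin <= 0):
            raise PlacementError(
                f"volume of extent {extent_um} µm is too small for an islet of "
                f"semi-axes {semi} µm"
            )
        for attempt in range(spec.max_retries):
            c_um = rng.uniform(margin, extent_um - margin)
            ok = all(
                np.linalg.norm(c_um - c2) > bound + b2 + spec.min_gap_um
                for c2, b2 in placed
            )
            if ok:
                break
        else:
            density = len(placed) / np.prod(extent_um / 1000.0)
            raise PlacementError(
                f"could not place islet {i} after {spec.max_retries} retries; "
                f"islet density {density:.3g} per 1000 µm³-cube is too high for "
                f"non-overlapping placement"
            )
        placed.append((c_um, bound))
        center_vox = (c_um[0] / dz, c_um[1] / dy, c_um[2] / dx)
        sl, m = _rasterize_ellipsoid(shape, spec.resolution, center_vox, semi)
        insulin[sl][m] = spec.islet_intensity
        islet_mask_labels[sl][m] = i
        bboxes[i] = sl
        islets.append(IsletTruth(i, center_vox, tuple(float(s) for s in semi), int(m.sum())))

    # --- Ki67 nuclei -------------------------------------------------------
    nuclei: list[tuple[int, tuple[int, int, int]]] = []
    centers = np.empty((0, 3))
    vv_um3 = dz * dy * dx
    for islet in islets:
        lam = spec.nuclei_per_islet_model * islet.voxels * vv_um3
        n_nuc = int(rng.poisson(lam))
        if n_nuc == 0:
            continue
        sl = bboxes[islet.islet_id]
        local = np.argwhere(islet_mask_labels[sl] == islet.islet_id)
        offset = np.array([s.start for s in sl])
        for _ in range(n_nuc):
            for attempt in range(spec.max_retries):
                c = local[rng.integers(len(local))] + offset
                if (len(centers) == 0
                        or np.min(np.linalg.norm(centers - c, axis=1))
                        >= spec.nucleus_min_separation_vox):
                    centers = np.vstack([centers, c.astype(float)])
                    nuclei.append((islet.islet_id, tuple(int(v) for v in c)))
                    break
            # silently drop a nucleus that cannot be separated: the truth
            # records only what was actually planted

    sigma_vox = np.array([spec.nucleus_radius / 2.0 / d for d in (dz, dy, dx)])
    for _, (cz_, cy_, cx_) in nuclei:
        _add_gaussian_blob(ki67, (cz_, cy_, cx_), sigma_vox, spec.nucleus_intensity)

    # --- CD45 infiltration -------------------------------------------------
    a, b = spec.infiltration_model
    infiltration: dict[int, int] = {}
    for islet in islets:
        frac = float(rng.beta(a, b))
        n_inf = int(round(frac * islet.voxels))
        infiltration[islet.islet_id] = n_inf
        if n_inf == 0:
            continue
        sl = bboxes[islet.islet_id]
        local = islet_mask_labels[sl] == islet.islet_id
        # peripheral shell first: voxels within shell_thickness of the surface
        dist = ndimage.distance_transform_edt(local, sampling=(dz, dy, dx))
        shell = local & (dist <= spec.shell_thickness_um)
        shell_idx = np.argwhere(shell)
        interior_idx = np.argwhere(local & ~shell)
        rng.shuffle(shell_idx)
        rng.shuffle(interior_idx)
        chosen = np.concatenate([shell_idx, interior_idx])[:n_inf]
        view = cd45[sl]
        view[tuple(chosen.T)] = spec.cd45_intensity

    # --- noise and 16-bit quantization -------------------------------------
    out = []
    for arr, name in ((insulin, "insulin"), (ki67, "ki67"), (cd45, "cd45")):
        if spec.poisson_noise:
            arr = rng.poisson(arr).astype(np.float64)
        if spec.noise_sd > 0:
            arr = arr + rng.normal(0.0, spec.noise_sd, size=arr.shape)
        arr = np.clip(np.rint(arr), 0, 65535).astype(np.uint16)
        out.append(ChannelVolume(arr, spec.resolution, name))

    truth = PhantomTruth(
        islets=islets, nuclei=nuclei, infiltration=infiltration,
        resolution=tuple(float(r) for r in spec.resolution), seed=spec.seed,
    )
    return out[0], out[1], out[2], truth


def _add_gaussian_blob(arr, center, sigma_vox, amplitude, truncate=4.0):
    shape = arr.shape
    cz, cy, cx = center
    ext = np.ceil(truncate * sigma_vox).astype(int)
    z0, z1 = max(cz - ext[0], 0), min(cz + ext[0] + 1, shape[0])
    y0, y1 = max(cy - ext[1], 0), min(cy + ext[1] + 1, shape[1])
    x0, x1 = max(cx - ext[2], 0), min(cx + ext[2] + 1, shape[2])
    zz = ((np.arange(z0, z1) - cz) / sigma_vox[0]) ** 2
    yy = ((np.arange(y0, y1) - cy) / sigma_vox[1]) ** 2
    xx = ((np.arange(x0, x1) - cx) / sigma_vox[2]) ** 2
    g = np.exp(-0.5 * (zz[:, None, None] + yy[None, :, None] + xx[None, None, :]))
    arr[z0:z1, y0:y1, x0:x1] += amplitude * g


def truth_to_records(truth: PhantomTruth, resolution) -> list[IsletRecord]:
    """Truth-derived islet records: volume from the rasterized voxel count,
    Ki67 count from planted nuclei, CD45 fraction from planted infiltration."""
    res = tuple(float(r) for r in resolution)
    if res != tuple(truth.resolution):
        raise ValueError(
            f"resolution {res} does not match the truth's recorded resolution "
            f"{truth.resolution}"
        )
    vv = res[0] * res[1] * res[2]
    records = []
    for islet in truth.islets:
        n_nuc = truth.nuclei_count(islet.islet_id)
        n_inf = truth.infiltration.get(islet.islet_id, 0)
        records.append(IsletRecord(
            islet_id=islet.islet_id,
            voxels=islet.voxels,
            volume_1000um3=islet.voxels * vv / 1000.0,
            centroid=islet.center_vox,
            ki67_count=n_nuc,
            ki67_positive=n_nuc >= 1,
            cd45_fraction=n_inf / islet.voxels,
        ))
    return records


def write_phantom(spec: PhantomSpec, out_dir: str | Path):
    """Generate a phantom and write per-channel multi-page TIFFs, a truth
    table CSV and a JSON sidecar with the spec and seed.  Returns the truth."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    insulin, ki67, cd45, truth = generate_phantom(spec)
    for vol in (insulin, ki67, cd45):
        write_volume(vol, out_dir / f"{vol.channel}.tif")
    rows = []
    for islet in truth.islets:
        cz, cy, cx = islet.center_vox
        az, ay, ax = islet.semi_axes_um
        rows.append({
            "islet_id": islet.islet_id, "cz": cz, "cy": cy, "cx": cx,
            "ax_um": ax, "ay_um": ay, "az_um": az, "voxels": islet.voxels,
            "n_nuclei": truth.nuclei_count(islet.islet_id),
            "infil_voxels": truth.infiltration.get(islet.islet_id, 0),
        })
    pd.DataFrame(rows, columns=["islet_id", "cz", "cy", "cx", "ax_um", "ay_um",
                                "az_um", "voxels", "n_nuclei", "infil_voxels"]
                 ).to_csv(out_dir / "truth.csv", index=False)
    pd.DataFrame([{"islet_id": i, "z": c[0], "y": c[1], "x": c[2]}
                  for i, c in truth.nuclei],
                 columns=["islet_id", "z", "y", "x"]
                 ).to_csv(out_dir / "nuclei.csv", index=False)
    sidecar = {"spec": dataclasses.asdict(spec), "seed": spec.seed}
    (out_dir / "phantom.json").write_text(json.dumps(sidecar, indent=2, default=list))
    return insulin, ki67, cd45, truth
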