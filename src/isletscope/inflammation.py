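"""Per-islet CD45 infiltration scoring and inflamed-islet classification.

Leukocyte infiltration is scored as the fraction of an islet's voxels that
are CD45⁺; an islet with at least 5% of its volume CD45⁺ is classified as
inflamed (the boundary counts: fraction == threshold is inflamed).
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .isletquant import BIN_NAMES, IsletRecord


def cd45_fraction_per_islet(cd45_mask: np.ndarray, islet_labels: np.ndarray) -> dict[int, float]:
    """CD45⁺ voxel fraction of each islet: |cd45 ∩ islet| / |islet|."""
    cd45_mask = np.asarray(cd45_mask)
    islet_labels = np.asarray(islet_labels)
    if cd45_mask.shape != islet_labels.shape:
        raise ValueError(
            f"shape mismatch: cd45 {cd45_mask.shape} vs labels {islet_labels.shape}"
        )
    vals = np.unique(cd45_mask)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("cd45 mask must be binary")
    n = int(islet_labels.max(initial=0))
    if n == 0:
        return {}
    totals = np.bincount(islet_labels.ravel(), minlength=n + 1)
    positives = np.bincount(islet_labels.ravel(), weights=cd45_mask.ravel().astype(np.float64),
                            minlength=n + 1)
    return {i: float(positives[i] / totals[i]) for i in range(1, n + 1) if totals[i] > 0}


def classify_inflamed(
    records: Sequence[IsletRecord],
    threshold: float = 0.05,
    fractions: dict[int, float] | None = None,
) -> tuple[list[IsletRecord], dict[str, float | None]]:
    """Flag inflamed islets and summarize per-bin inflamed percentages.

    ``fractions`` (per islet id) fill ``cd45_fraction`` when the records do
    not carry one yet.  An islet is inflamed iff its fraction >= threshold.
    Bins with zero islets report ``None`` (undefined), not 0.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    out = []
    for r in records:
        if fractions is not None and r.islet_id in fractions:
            r.cd45_fraction = float(fractions[r.islet_id])
        if r.cd45_fraction is None:
            raise ValueError(f"record {r.islet_id} has no cd45_fraction")
        r.inflamed = r.cd45_fraction >= threshold
        out.append(r)

    per_bin: dict[str, float | None] = {}
    for b in BIN_NAMES:
        in_bin = [r for r in out if r.bin == b]
        if not in_bin:
            per_bin[b] = None
        else:
            per_bin[b] = 100.0 * sum(r.inflamed for r in in_bin) / len(in_bin)
    return out, per_bin
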