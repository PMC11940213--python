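"""Per-ganglion measurements and per-subject summaries.

A segmentation mask applied to a T2 map yields one measurement per ganglion
(DRG sample): a within-VOI T2 summary plus the volume (voxel count times voxel
volume).  Reader-specific samples are averaged into a consensus, and each
subject is summarised as the mean over their DRG samples (overall and per
level), which is the unit of all cohort statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fitting import T2MapVolume

__all__ = [
    "DRGSample",
    "extract_voi",
    "compute_volume",
    "average_readers",
    "summarise_subject",
    "summarise_subjects",
]

#: Canonical column order of a tidy DRG-sample table.
SAMPLE_COLUMNS = [
    "subject_id",
    "visit",
    "reader",
    "level",
    "side",
    "t2_ms",
    "volume_mm3",
]


@dataclass(frozen=True)
class DRGSample:
    """One ganglion measurement."""

    subject_id: str
    visit: str  # baseline | retest
    reader: str  # reader id or "consensus"
    level: str  # L5 | S1
    side: str  # left | right
    t2_ms: float
    volume_mm3: float
    n_voxels: int | None = None


def extract_voi(
    t2_map: T2MapVolume,
    mask: np.ndarray,
    label: int,
    summary: str = "median",
    mask_affine: np.ndarray | None = None,
) -> tuple[float, int]:
    """Within-VOI T2 summary under ``label``.

    Only fitted voxels enter the summary (default median; ``mean`` by
    argument); unfittable voxels under the label are counted and excluded.
    Returns ``(t2_ms, n_voxels)`` where ``n_voxels`` is the full label size
    (segmentation defines volume, not fit success).
    """
    if summary not in ("median", "mean"):
        raise ValueError("summary must be 'median' or 'mean'")
    mask = np.asarray(mask)
    if mask.shape != t2_map.t2_ms.shape:
        raise ValueError("mask and T2 map shapes differ")
    if mask_affine is not None and not np.allclose(mask_affine, t2_map.affine):
        raise ValueError("mask and T2 map affines differ")
    in_label = mask == label
    n_voxels = int(in_label.sum())
    if n_voxels == 0:
        raise ValueError(f"label {label} is empty")
    usable = in_label & t2_map.fitted_mask
    n_excluded = n_voxels - int(usable.sum())
    if not usable.any():
        raise ValueError(f"label {label}: all voxels unfittable")
    vals = t2_map.t2_ms[usable]
    t2 = float(np.median(vals) if summary == "median" else np.mean(vals))
    if n_excluded:
        import logging

        logging.getLogger(__name__).info(
            "label %d: excluded %d unfittable voxel(s) from T2 summary",
            label,
            n_excluded,
        )
    return t2, n_voxels


def compute_volume(mask: np.ndarray, label: int, voxel_dims_mm) -> float:
    """Volume of a label: voxel count times voxel volume (dx·dy·dz)."""
    mask = np.asarray(mask)
    n = int((mask == label).sum())
    if n == 0:
        raise ValueError(f"label {label} is empty")
    return n * float(np.prod(voxel_dims_mm))


def average_readers(samples: pd.DataFrame, readers=None) -> pd.DataFrame:
    """Consensus samples: arithmetic mean of T2 and volume across readers.

    Every (subject, visit, level, side) group must contain exactly the
    configured reader set (default: all readers present in the table);
    missing readers raise with the offending groups listed.
    """
    df = samples.copy()
    if readers is None:
        readers = sorted(df["reader"].unique())
    readers = list(readers)
    keys = ["subject_id", "visit", "level", "side"]
    gaps = []
    for key, grp in df.groupby(keys):
        present = sorted(grp["reader"].unique())
        if present != sorted(readers):
            gaps.append((key, present))
    if gaps:
        raise ValueError(f"incomplete reader sets for {len(gaps)} group(s): {gaps[:5]}")
    out = (
        df[df["reader"].isin(readers)]
        .groupby(keys, as_index=False)[["t2_ms", "volume_mm3"]]
        .mean()
    )
    out.insert(2, "reader", "consensus")
    return out[SAMPLE_COLUMNS]


def summarise_subject(samples: pd.DataFrame) -> dict:
    """Mean over one subject-visit's DRG samples, overall and per level."""
    if len(samples) == 0:
        raise ValueError("no samples to summarise")
    out = {
        "drg_t2_ms": float(samples["t2_ms"].mean()),
        "drg_vol_mm3": float(samples["volume_mm3"].mean()),
        "n_drg": int(len(samples)),
    }
    for level in ("L5", "S1"):
        sub = samples[samples["level"] == level]
        out[f"drg_t2_{level.lower()}_ms"] = (
            float(sub["t2_ms"].mean()) if len(sub) else np.nan
        )
        out[f"drg_vol_{level.lower()}_mm3"] = (
            float(sub["volume_mm3"].mean()) if len(sub) else np.nan
        )
    return out


def summarise_subjects(samples: pd.DataFrame) -> pd.DataFrame:
    """Apply :func:`summarise_subject` per (subject, visit)."""
    rows = []
    for (sid, visit), grp in samples.groupby(["subject_id", "visit"]):
        row = {"subject_id": sid, "visit": visit}
        row.update(summarise_subject(grp))
        rows.append(row)
    return pd.DataFrame(rows)
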