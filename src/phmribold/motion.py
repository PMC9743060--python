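"""Motion quality control: per-subject summaries and the half-voxel rule.

Awake-animal imaging tolerates no realignment here; subjects whose
in-plane head displacement exceeds half of one voxel are excluded
outright. With 187.5 um in-plane resolution the default threshold is
93.75 um. Displacements are measured relative to the first (reference)
acquisition; the through-plane (Z) axis is summarised but never triggers
exclusion.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic import MotionTrace

__all__ = [
    "MotionSummary",
    "HALF_VOXEL_UM",
    "summarize_motion",
    "apply_exclusion",
    "read_motion_tsv",
    "write_motion_summaries",
]

#: half of the 187.5 um in-plane voxel edge
HALF_VOXEL_UM = 93.75

_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class MotionSummary:
    """Axis-wise displacement statistics (um) and the exclusion verdict."""

    subject_id: str
    mean_um: tuple[float, float, float]
    sd_um: tuple[float, float, float]
    max_um: tuple[float, float, float]   # maximum absolute displacement
    excluded: bool = False
    reason: str = ""


def summarize_motion(trace: MotionTrace) -> MotionSummary:
    """Mean, SD (population formula) and maximum absolute displacement
    per axis over all acquisitions."""
    d = np.asarray(trace.displacement_um, dtype=float)
    if d.shape[0] == 0:
        raise ValueError("motion trace is empty")
    return MotionSummary(
        subject_id=trace.subject_id,
        mean_um=tuple(d.mean(axis=0)),
        sd_um=tuple(d.std(axis=0)),  # ddof=0
        max_um=tuple(np.abs(d).max(axis=0)),
    )


def apply_exclusion(
    summary: MotionSummary, half_voxel_um: float = HALF_VOXEL_UM
) -> MotionSummary:
    """Exclude the subject iff any in-plane (X or Y) maximum absolute
    displacement strictly exceeds ``half_voxel_um``.

    The through-plane axis is reported but never excluding. The boundary
    is retained: motion of exactly half a voxel keeps the subject.
    """
    if half_voxel_um <= 0:
        raise ValueError("half_voxel_um must be positive")
    offending = [
        (ax, m)
        for ax, m in zip(_AXES[:2], summary.max_um[:2])
        if m > half_voxel_um
    ]
    if offending:
        reason = "; ".join(
            f"max |{ax.upper()}| displacement {m:.1f} um > {half_voxel_um:g} um"
            for ax, m in offending
        )
        return replace(summary, excluded=True, reason=reason)
    return replace(summary, excluded=False, reason="")


def read_motion_tsv(path: str | Path, subject_id: str = "") -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    return MotionTrace(
        displacement_um=df[["x_um", "y_um", "z_um"]].to_numpy(float),
        subject_id=subject_id,
    )


def write_motion_summaries(summaries, path: str | Path) -> pd.DataFrame:
    """One TSV row per subject with the axis statistics and verdict."""
    rows = []
    for s in summaries:
        row = {"subject_id": s.subject_id}
        for i, ax in enumerate(_AXES):
            row[f"mean_{ax}_um"] = s.mean_um[i]
            row[f"sd_{ax}_um"] = s.sd_um[i]
            row[f"max_{ax}_um"] = s.max_um[i]
        row["excluded"] = s.excluded
        row["reason"] = s.reason
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False)
    return df
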