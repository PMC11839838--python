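"""Stack per-slice best masks into 3D volumes, fuse orientations by majority
vote, and score with volumetric Dice.

Slices with no trace (no tumor ground truth, hence never evaluated)
contribute background: the stacked volume is zero outside traced planes by
construction, and an orientation that did not cover a voxel simply votes
background for it in the fusion.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from promptseg.volume_prep import ORIENTATION_AXIS

PROVENANCES = tuple(ORIENTATION_AXIS) + ("fused",)


@dataclass
class MaskVolume:
    """A binary segmentation on the full study grid with its provenance."""

    data: np.ndarray
    orientation: str  # transverse | sagittal | coronal | fused
    study_id: str

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise ValueError("MaskVolume data must be 3D")
        if self.orientation not in PROVENANCES:
            raise ValueError(f"unknown provenance {self.orientation!r}")


def stack_traces(records: Sequence, grid_shape: tuple) -> MaskVolume:
    """Stack the best-iteration selected masks of one orientation into 3D.

    ``records`` are :class:`~promptseg.prompt_sim.TraceRecord` objects sharing
    one study and orientation, at most one per slice index. Cropped-mode
    masks are mapped back to the full grid via the recorded ROI offset.
    """
    if len(records) == 0:
        raise ValueError("no traces to stack")
    study_ids = {r.study_id for r in records}
    orientations = {r.orientation for r in records}
    if len(study_ids) != 1 or len(orientations) != 1:
        raise ValueError("traces must share one study_id and one orientation")
    orientation = orientations.pop()
    axis = ORIENTATION_AXIS[orientation]
    inplane_axes = [a for a in range(3) if a != axis]

    volume = np.zeros(grid_shape, dtype=bool)
    seen = set()
    for rec in records:
        mask = rec.trace.best_mask
        offset = rec.roi_lower if rec.roi_lower is not None else (0, 0, 0)
        full_index = rec.trace.sample.slice_index + offset[axis]
        if full_index in seen:
            raise ValueError(f"duplicate slice index {full_index}")
        seen.add(full_index)
        r0 = offset[inplane_axes[0]]
        c0 = offset[inplane_axes[1]]
        sl = [slice(None)] * 3
        sl[axis] = full_index
        sl[inplane_axes[0]] = slice(r0, r0 + mask.shape[0])
        sl[inplane_axes[1]] = slice(c0, c0 + mask.shape[1])
        volume[tuple(sl)] = mask
    return MaskVolume(data=volume, orientation=orientation, study_id=study_ids.pop())


def majority_vote(v1: MaskVolume, v2: MaskVolume, v3: MaskVolume) -> MaskVolume:
    """Per-voxel 2-of-3 majority vote of three mask volumes."""
    vols = (v1, v2, v3)
    shapes = {v.data.shape for v in vols}
    studies = {v.study_id for v in vols}
    if len(shapes) != 1:
        raise ValueError("grid mismatch between mask volumes")
    if len(studies) != 1:
        raise ValueError("mask volumes belong to different studies")
    votes = sum(v.data.astype(np.uint8) for v in vols)
    return MaskVolume(data=votes >= 2, orientation="fused", study_id=studies.pop())


def volumetric_dice(pred: MaskVolume | np.ndarray, gt: np.ndarray) -> float:
    """Volumetric Dice 2|A∩B| / (|A|+|B|); 1.0 when both are empty."""
    a = pred.data if isinstance(pred, MaskVolume) else np.asarray(pred, dtype=bool)
    b = np.asarray(gt, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"shapes differ: {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
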