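"""Interactive point-prompt simulation per slice with triple-mask selection.

The simulated workflow mirrors an expert interactively segmenting a tumor on
one 2D slice with a promptable model:

1. the first foreground point goes at the tumor center (ground-truth distance
   transform argmax);
2. the model returns three candidate masks with confidence scores; one is
   selected by the strategy under evaluation (``oracle`` — highest calculated
   IoU against ground truth; ``suggested`` — highest model confidence;
   ``prev_slice`` — most similar to the previous slice's segmentation);
3. each corrective point goes at the center of the set difference between
   ground truth and the selected mask — a foreground point when the ground
   truth area is at least the predicted area, else a background point;
4. the calculated IoU of the selected mask is recorded per iteration, up to a
   cap of nine points; the best IoU over iterations is the primary per-slice
   metric.

"Center" of a region means the Euclidean distance-transform argmax within the
largest 8-connected component — unlike a centroid it always lies inside the
region, even for concave shapes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from promptseg.phantoms import LabeledVolume, SliceRegistry
from promptseg.volume_prep import (
    SliceSample,
    crop,
    extract_slices,
    fit_roi,
    normalize_volume,
)

STRATEGIES = ("oracle", "suggested", "prev_slice")
MAX_POINTS_DEFAULT = 9

_EIGHT_CONN = np.ones((3, 3), dtype=bool)


@dataclass(frozen=True)
class PromptPoint:
    """A single point prompt: pixel position, label, and iteration placed."""

    row: int
    col: int
    label: str  # "foreground" | "background"
    iteration: int

    def __post_init__(self) -> None:
        if self.label not in ("foreground", "background"):
            raise ValueError(f"bad prompt label {self.label!r}")


@dataclass
class PredictionTriple:
    """Three candidate binary masks plus model-reported confidences."""

    masks: tuple
    confidences: tuple

    def __post_init__(self) -> None:
        if len(self.masks) != 3 or len(self.confidences) != 3:
            raise ValueError("a PredictionTriple holds exactly 3 masks + scores")
        shapes = {np.asarray(m).shape for m in self.masks}
        if len(shapes) != 1:
            raise ValueError("candidate masks have mismatched shapes")
        if not all(np.isfinite(c) for c in self.confidences):
            raise ValueError("confidences must be finite")


class PromptablePredictor(Protocol):
    """Contract for any promptable model adapter.

    A callable taking a 3-channel 2D image and an ordered prompt list and
    returning a :class:`PredictionTriple`; deterministic and stateless for
    fixed inputs (and fixed internal seed).
    """

    def __call__(
        self, image: np.ndarray, prompts: Sequence[PromptPoint]
    ) -> PredictionTriple: ...


#: Plug-in registry so real model adapters can be added without touching
#: this module. Factories take (predictor_config: dict, registry, seed).
PREDICTOR_REGISTRY: dict[str, Callable] = {}


def register_predictor(name: str):
    def deco(factory):
        PREDICTOR_REGISTRY[name] = factory
        return factory

    return deco


@register_predictor("mock")
def _mock_factory(config: dict, registry: SliceRegistry, seed: int):
    from promptseg.phantoms import MockPredictorParams, make_mock_predictor

    params = MockPredictorParams(**{**config, "seed": seed})
    return make_mock_predictor(params, registry)


@dataclass
class IterationRecord:
    """State after one prompt iteration of one slice."""

    iteration: int
    selected_index: int
    selected_mask: np.ndarray
    iou: float
    candidate_ious: tuple
    confidences: tuple


@dataclass
class SliceTrace:
    """Full per-iteration record of the interactive loop on one slice."""

    sample: SliceSample
    strategy: str
    prompts: list
    iterations: list
    best_iou: float
    best_iteration: int
    terminated_early: bool

    @property
    def best_mask(self) -> np.ndarray:
        return self.iterations[self.best_iteration - 1].selected_mask

    @property
    def iou_curve(self) -> np.ndarray:
        return np.array([r.iou for r in self.iterations])


def compute_iou(a: np.ndarray, b: np.ndarray) -> float:
    """Intersection over union of two binary masks; 1.0 if both empty."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(a, b).sum() / union)


def _dt_argmax(region: np.ndarray) -> tuple[int, int]:
    """Distance-transform argmax of a region; first occurrence in row-major
    order breaks exact ties, i.e. the lexicographically smallest pixel."""
    dt = ndimage.distance_transform_edt(region)
    r, c = np.unravel_index(int(np.argmax(dt)), dt.shape)
    return int(r), int(c)


def place_initial_point(gt: np.ndarray) -> PromptPoint:
    """Initial foreground prompt at the tumor center: the ground-truth
    distance-transform argmax."""
    gt = np.asarray(gt, dtype=bool)
    if not gt.any():
        raise ValueError("cannot place a point on an empty mask")
    r, c = _dt_argmax(gt)
    return PromptPoint(row=r, col=c, label="foreground", iteration=1)


def _largest_component(region: np.ndarray) -> np.ndarray:
    labels, n = ndimage.label(region, structure=_EIGHT_CONN)
    if n == 1:
        return region
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    best = sizes.max()
    tied = np.flatnonzero(sizes == best)
    if len(tied) == 1:
        return labels == tied[0]
    # tie: component containing the lexicographically smallest pixel
    flat = labels.ravel()
    first = {lab: np.argmax(flat == lab) for lab in tied}
    winner = min(tied, key=lambda lab: first[lab])
    return labels == winner


def next_prompt(gt: np.ndarray, pred: np.ndarray, iteration: int) -> PromptPoint:
    """Corrective prompt: center of the set difference between ground truth
    and prediction.

    Foreground when the ground-truth area is >= the predicted area (point in
    ``gt \\ pred``), else background (point in ``pred \\ gt``); the point is
    the distance-transform argmax of the largest 8-connected component of the
    chosen difference, so it always lies inside it.
    """
    gt = np.asarray(gt, dtype=bool)
    pred = np.asarray(pred, dtype=bool)
    if gt.shape != pred.shape:
        raise ValueError("mask shapes differ")
    if np.array_equal(gt, pred):
        raise ValueError("gt == pred: both set differences are empty")
    foreground = int(gt.sum()) >= int(pred.sum())
    diff = (gt & ~pred) if foreground else (pred & ~gt)
    component = _largest_component(diff)
    r, c = _dt_argmax(component)
    return PromptPoint(
        row=r,
        col=c,
        label="foreground" if foreground else "background",
        iteration=iteration,
    )


def select_mask(
    triple: PredictionTriple,
    gt: np.ndarray,
    strategy: str,
    prev_mask: Optional[np.ndarray] = None,
):
    """Pick one of the three candidates; ties go to the lowest index.

    oracle: argmax calculated IoU vs ground truth. suggested: argmax reported
    confidence. prev_slice: argmax IoU vs the previous slice's segmentation.
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}")
    if strategy == "oracle":
        scores = [compute_iou(m, gt) for m in triple.masks]
    elif strategy == "suggested":
        scores = list(triple.confidences)
    else:
        if prev_mask is None:
            raise ValueError("prev_slice strategy requires prev_mask")
        scores = [compute_iou(m, prev_mask) for m in triple.masks]
    idx = int(np.argmax(scores))
    return np.asarray(triple.masks[idx], dtype=bool), idx


def simulate_slice(
    sample: SliceSample,
    predictor: PromptablePredictor,
    strategy: str = "oracle",
    max_points: int = MAX_POINTS_DEFAULT,
    prev_mask: Optional[np.ndarray] = None,
) -> SliceTrace:
    """Run the full interactive loop on one slice and return its trace.

    Terminates early when the selected mask equals the ground truth (both set
    differences are then empty, so no further prompt is defined).
    """
    gt = sample.gt_mask
    prompts = [place_initial_point(gt)]
    records: list[IterationRecord] = []
    selected = None
    terminated_early = False

    for it in range(1, max_points + 1):
        if it > 1:
            prompts.append(next_prompt(gt, selected, iteration=it))
        triple = predictor(sample.image, prompts)
        for k, m in enumerate(triple.masks):
            if np.asarray(m).shape != gt.shape:
                raise ValueError(
                    f"predictor candidate {k} has shape {np.asarray(m).shape}, "
                    f"expected {gt.shape}"
                )
        selected, idx = select_mask(triple, gt, strategy, prev_mask)
        cand_ious = tuple(compute_iou(m, gt) for m in triple.masks)
        records.append(
            IterationRecord(
                iteration=it,
                selected_index=idx,
                selected_mask=selected,
                iou=cand_ious[idx],
                candidate_ious=cand_ious,
                confidences=tuple(float(c) for c in triple.confidences),
            )
        )
        if np.array_equal(selected, gt):
            terminated_early = it < max_points
            break

    ious = [r.iou for r in records]
    best_iteration = int(np.argmax(ious)) + 1  # first argmax
    return SliceTrace(
        sample=sample,
        strategy=strategy,
        prompts=prompts,
        iterations=records,
        best_iou=float(max(ious)),
        best_iteration=best_iteration,
        terminated_early=terminated_early,
    )


# ---------------------------------------------------------------------------
# Study driver
# ---------------------------------------------------------------------------


@dataclass
class TraceRecord:
    """A slice trace plus the experiment arm it belongs to."""

    trace: SliceTrace
    study_id: str
    orientation: str
    strategy: str
    cropped: bool
    roi_lower: Optional[tuple] = None  # full-grid offset for cropped-mode masks


@dataclass
class StudyResult:
    """All traces of a study plus tabular views and aggregates."""

    records: list
    grid_shapes: dict  # study_id -> full grid shape
    gt_masks: dict  # study_id -> full-grid ground truth

    def trace_table(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            t = rec.trace
            rows.append(
                {
                    "study_id": rec.study_id,
                    "orientation": rec.orientation,
                    "strategy": rec.strategy,
                    "cropped": rec.cropped,
                    "slice_index": t.sample.slice_index,
                    "grade": t.sample.grade,
                    "gt_area_mm2": t.sample.gt_area_mm2,
                    "best_iou": t.best_iou,
                    "best_iteration": t.best_iteration,
                    "n_iterations": len(t.iterations),
                    "terminated_early": t.terminated_early,
                    "iou_curve": ";".join(f"{r.iou:.6f}" for r in t.iterations),
                    "prompts": ";".join(
                        f"{p.row},{p.col},{p.label[0]}" for p in t.prompts
                    ),
                }
            )
        return pd.DataFrame(rows)

    def aggregate(self) -> pd.DataFrame:
        """Per-arm summary: n, mean best IoU, IQR, mean prompts to best,
        plus per-grade splits."""
        df = self.trace_table()
        out = []
        group_cols = ["strategy", "cropped", "orientation"]
        for keys, g in df.groupby(group_cols, sort=True):
            for grade in ["all"] + sorted(g["grade"].unique()):
                sub = g if grade == "all" else g[g["grade"] == grade]
                if sub.empty:
                    continue
                q25, q75 = np.percentile(sub["best_iou"], [25, 75])
                out.append(
                    dict(
                        zip(group_cols, keys),
                        grade=grade,
                        n_slices=len(sub),
                        mean_best_iou=sub["best_iou"].mean(),
                        iqr_low=q25,
                        iqr_high=q75,
                        mean_prompts_to_best=sub["best_iteration"].mean(),
                    )
                )
        return pd.DataFrame(out)


def run_study(
    volumes: Sequence[LabeledVolume],
    predictor: PromptablePredictor,
    strategies: Sequence[str] = ("oracle",),
    orientations: Sequence[str] = ("transverse",),
    cropped: bool | Sequence[bool] = False,
    max_points: int = MAX_POINTS_DEFAULT,
    margin_mm: float = 20.0,
    registry: Optional[SliceRegistry] = None,
    progress: Optional[Callable[[str], None]] = None,
) -> StudyResult:
    """Enumerate volume x orientation x strategy x (full|cropped) arms and
    simulate every tumor-containing slice.

    Volumes are normalized at dataset level before anything else; cropped
    arms fit the tumor ROI with ``margin_mm`` on the normalized volume and
    record the ROI offset so cropped-frame masks map back to the full grid
    for fusion. When a :class:`~promptseg.phantoms.SliceRegistry` is given,
    every extracted slice (full and cropped) is registered before
    simulation so the mock predictor can look up its ground truth.

    ``prev_slice`` runs sequentially in ascending slice order, selecting the
    candidate most similar to the previous slice's best mask; the first
    tumor-containing slice of each volume falls back to oracle selection.
    """
    if len(volumes) == 0:
        raise ValueError("empty volume list")
    cropped_arms = (cropped,) if isinstance(cropped, bool) else tuple(cropped)
    for s in strategies:
        if s not in STRATEGIES:
            raise ValueError(f"unknown strategy {s!r}")

    records: list[TraceRecord] = []
    grid_shapes: dict[str, tuple] = {}
    gt_masks: dict[str, np.ndarray] = {}

    for vol in volumes:
        norm = normalize_volume(vol)
        grid_shapes[vol.study_id] = norm.gt_mask.shape
        gt_masks[vol.study_id] = norm.gt_mask
        if registry is not None:
            from promptseg.phantoms import estimate_volume_contrast

            study_contrast = estimate_volume_contrast(norm)
        for is_cropped in cropped_arms:
            if is_cropped:
                box = fit_roi(norm, margin_mm)
                work, roi_lower = crop(norm, box), tuple(box.lower)
            else:
                work, roi_lower = norm, None
            for orientation in orientations:
                samples = extract_slices(work, orientation)
                if registry is not None:
                    for s in samples:
                        registry.register_sample(s, contrast=study_contrast)
                for strategy in strategies:
                    prev_mask = None
                    for sample in samples:
                        if strategy == "prev_slice" and prev_mask is None:
                            trace = simulate_slice(
                                sample, predictor, "oracle", max_points
                            )
                            trace.strategy = "prev_slice"
                        else:
                            trace = simulate_slice(
                                sample, predictor, strategy, max_points,
                                prev_mask=prev_mask,
                            )
                        if strategy == "prev_slice":
                            prev_mask = trace.best_mask
                        records.append(
                            TraceRecord(
                                trace=trace,
                                study_id=vol.study_id,
                                orientation=orientation,
                                strategy=strategy,
                                cropped=bool(is_cropped),
                                roi_lower=roi_lower,
                            )
                        )
                    if progress is not None:
                        progress(
                            f"{vol.study_id} {orientation} {strategy} "
                            f"cropped={bool(is_cropped)}: {len(samples)} slices"
                        )
    return StudyResult(records=records, grid_shapes=grid_shapes, gt_masks=gt_masks)
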