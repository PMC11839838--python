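"""Volume normalization, per-orientation slice extraction, and ROI cropping.

Conventions (fixed so that stacking and fusion are bit-stable):

* voxel indices are 0-based; boxes are half-open ``[lower, upper)``;
* orientation axes: sagittal = axis 0, coronal = axis 1, transverse = axis 2.
  For NIfTI volumes read with :func:`read_labeled_volume` this matches RAS
  data arrays (axis 0 left-right, axis 1 posterior-anterior, axis 2
  inferior-superior).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from promptseg.phantoms import LabeledVolume

ORIENTATION_AXIS = {"sagittal": 0, "coronal": 1, "transverse": 2}
ORIENTATIONS = tuple(ORIENTATION_AXIS)


@dataclass
class SliceSample:
    """One tumor-containing 2D slice: 3-channel 8-bit image + ground truth.

    ``gt_area_mm2`` is the foreground pixel count times the in-plane pixel
    area (exact on isotropic grids).
    """

    image: np.ndarray  # (H, W, 3) uint8, all channels identical
    gt_mask: np.ndarray  # (H, W) bool, nonempty
    orientation: str
    slice_index: int
    study_id: str
    grade: str
    gt_area_mm2: float

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image)
        self.gt_mask = np.asarray(self.gt_mask).astype(bool)
        if self.image.ndim != 3 or self.image.shape[-1] != 3:
            raise ValueError("image must be (H, W, 3)")
        if self.image.shape[:2] != self.gt_mask.shape:
            raise ValueError("image and gt_mask shapes differ")
        if not self.gt_mask.any():
            raise ValueError("gt_mask is empty: only tumor-containing slices exist")
        if self.orientation not in ORIENTATION_AXIS:
            raise ValueError(f"unknown orientation {self.orientation!r}")


@dataclass(frozen=True)
class RoiBox:
    """Cuboid ROI in voxel indices, half-open per axis."""

    lower: tuple[int, int, int]
    upper: tuple[int, int, int]
    margin_mm: float

    def __post_init__(self) -> None:
        if any(l >= u for l, u in zip(self.lower, self.upper)):
            raise ValueError("RoiBox requires lower < upper on every axis")
        if self.margin_mm < 0:
            raise ValueError("margin_mm must be nonnegative")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(l, u) for l, u in zip(self.lower, self.upper))


def normalize_volume(vol: LabeledVolume) -> LabeledVolume:
    """Rescale intensities to the 8-bit range by the dataset maximum.

    Every voxel maps to ``round(v / max * 255)`` with round-half-up, so the
    maximum voxel maps to exactly 255. Normalization is per 3D dataset and is
    applied before any cropping, so cropped and full-slice experiments share
    intensities.

    Raises
    ------
    ValueError
        For an all-zero volume (normalization undefined).
    """
    vmax = float(vol.intensities.max())
    if vmax <= 0:
        raise ValueError("cannot normalize an all-zero volume")
    scaled = np.floor(vol.intensities.astype(float) / vmax * 255.0 + 0.5)
    return LabeledVolume(
        intensities=scaled.astype(np.uint8),
        gt_mask=vol.gt_mask,
        spacing_mm=vol.spacing_mm,
        grade=vol.grade,
        study_id=vol.study_id,
    )


def extract_slices(vol: LabeledVolume, orientation: str) -> list[SliceSample]:
    """Extract every tumor-containing 2D slice along an orientation axis.

    One :class:`SliceSample` per plane index whose ground-truth plane is
    nonempty, in ascending index order; intensities are replicated across
    three identical channels to satisfy the predictor input contract.
    """
    axis = ORIENTATION_AXIS[orientation]
    inplane_axes = [a for a in range(3) if a != axis]
    pixel_area = float(np.prod([vol.spacing_mm[a] for a in inplane_axes]))

    intens = vol.intensities
    if not np.issubdtype(intens.dtype, np.integer):
        raise ValueError("volume must be normalized to integer 8-bit range first")

    samples: list[SliceSample] = []
    for idx in range(vol.gt_mask.shape[axis]):
        gt_plane = np.take(vol.gt_mask, idx, axis=axis)
        n_fg = int(gt_plane.sum())
        if n_fg == 0:
            continue
        plane = np.take(intens, idx, axis=axis).astype(np.uint8)
        image = np.repeat(plane[..., None], 3, axis=-1)
        samples.append(
            SliceSample(
                image=image,
                gt_mask=gt_plane,
                orientation=orientation,
                slice_index=idx,
                study_id=vol.study_id,
                grade=vol.grade,
                gt_area_mm2=n_fg * pixel_area,
            )
        )
    return samples


def fit_roi(vol: LabeledVolume, margin_mm: float = 20.0) -> RoiBox:
    """Cuboid ROI fitted to the 3D tumor extent with a physical margin.

    Per axis: ``[min_fg - round(margin/spacing), max_fg + round(margin/spacing) + 1)``,
    clipped to the grid.
    """
    if not vol.gt_mask.any():
        raise ValueError("gt_mask is empty")
    fg = np.argwhere(vol.gt_mask)
    lower, upper = [], []
    for ax in range(3):
        mv = int(round(margin_mm / vol.spacing_mm[ax]))
        lo = max(0, int(fg[:, ax].min()) - mv)
        up = min(vol.gt_mask.shape[ax], int(fg[:, ax].max()) + 1 + mv)
        lower.append(lo)
        upper.append(up)
    return RoiBox(lower=tuple(lower), upper=tuple(upper), margin_mm=float(margin_mm))


def crop(vol: LabeledVolume, box: RoiBox) -> LabeledVolume:
    """Crop a volume to an ROI box; ``box.lower`` is the offset back to the
    full grid."""
    sl = box.slices
    return LabeledVolume(
        intensities=vol.intensities[sl].copy(),
        gt_mask=vol.gt_mask[sl].copy(),
        spacing_mm=vol.spacing_mm,
        grade=vol.grade,
        study_id=vol.study_id,
    )


# ---------------------------------------------------------------------------
# NIfTI IO
# ---------------------------------------------------------------------------


def write_labeled_volume(vol: LabeledVolume, image_path, label_path) -> None:
    """Write a labeled volume as a NIfTI image/label pair."""
    import nibabel as nib

    affine = np.diag(list(vol.spacing_mm) + [1.0])
    nib.save(nib.Nifti1Image(vol.intensities.astype(np.float32), affine), str(image_path))
    nib.save(nib.Nifti1Image(vol.gt_mask.astype(np.uint8), affine), str(label_path))


def read_labeled_volume(
    image_path,
    label_path,
    core_classes=None,
    grade: str = "HGG_like",
    study_id: str | None = None,
) -> LabeledVolume:
    """Read a NIfTI image/label pair into a :class:`LabeledVolume`.

    The label is binarized as ``value > 0``; pass ``core_classes`` (e.g.
    ``{1, 4}`` for necrotic + enhancing on multi-class glioma labels) to
    restrict the mask to the tumor-core subset first. Spacing comes from the
    image header.

    Raises
    ------
    ValueError
        On grid-shape or affine mismatch between image and label.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    lab = nib.load(str(label_path))
    if img.shape != lab.shape:
        raise ValueError(f"image shape {img.shape} != label shape {lab.shape}")
    if not np.allclose(img.affine, lab.affine, atol=1e-4):
        raise ValueError("image and label affines differ")
    data = np.asarray(img.dataobj, dtype=float)
    label = np.asarray(lab.dataobj)
    if core_classes is not None:
        mask = np.isin(label, list(core_classes))
    else:
        mask = label > 0
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    if study_id is None:
        import os

        study_id = os.path.basename(str(image_path)).split(".")[0]
    return LabeledVolume(
        intensities=data,
        gt_mask=mask,
        spacing_mm=spacing,
        grade=grade,
        study_id=study_id,
    )
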