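"""Synthetic labeled tumor volumes and a mock promptable predictor.

The phantom emulates the kind of input the pipeline sees on real
contrast-enhanced T1-weighted brain MRI: a noisy brain-like background
ellipsoid, a multi-lobed tumor core with a bright enhancing rim and a dimmed
necrotic interior, and a binary ground-truth mask covering the whole core
(necrotic plus enhancing). A ``rim_contrast`` axis spans sharp, high-contrast
lesions (high-grade-glioma-like) down to diffuse, low-contrast ones
(low-grade-glioma-like).

The mock predictor stands in for a promptable segmentation network: given a
3-channel 2D image and an ordered prompt list it returns three candidate
masks with confidence scores. Candidates are the slice ground truth degraded
by seeded morphological noise whose magnitude shrinks with the number of
prompts and grows as image contrast drops, so every qualitative behavior the
pipeline measures (prompt convergence, grade effect, imperfect confidence
ranking) is present without any model weights.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from promptseg._seeds import derive_seed

GRADE_HGG = "HGG_like"
GRADE_LGG = "LGG_like"

#: Pixels within this Chebyshev-ball radius of a prompt are forced to agree
#: with the prompt's label when a candidate mask contradicts it.
PROMPT_INFLUENCE_RADIUS = 3

# Intensity model (arbitrary scanner units, pre-normalization).
_BRAIN_BASE = 300.0
_OUTSIDE_BASE = 20.0
_RIM_GAIN = 500.0
_ENHANCING_GAIN = 250.0
_NECROTIC_LEVEL = 150.0
_TEXTURE_SD = 25.0


@dataclass(frozen=True)
class PhantomParams:
    """Parameters of one synthetic labeled volume.

    Attributes
    ----------
    grid_shape : tuple of int
        Voxel grid, all axes >= 16.
    spacing_mm : tuple of float
        Voxel spacing per axis in mm.
    n_lobes : int
        Number of ellipsoidal lobes forming the tumor core (shape
        complexity); the first lobe is a sphere of radius ``tumor_radius_mm``.
    tumor_radius_mm : float
        Radius scale of the core.
    rim_contrast : float in [0, 1]
        Brightness of the enhancing rim relative to brain background:
        high values give sharp HGG-like lesions, low values diffuse LGG-like.
    noise_sd : float
        SD of additive Gaussian intensity noise.
    necrotic_fraction : float in [0, 1)
        Fraction of the core volume (innermost, by distance transform) whose
        intensity is dimmed. The necrotic interior remains part of the
        ground-truth mask: the segmentation target is the whole tumor core.
    smooth_sigma : float
        Gaussian smoothing (voxels) applied to the lobe-union indicator
        before re-thresholding; 0 disables smoothing.
    seed : int
        Seed; identical params + seed give bit-identical volumes.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_lobes: int = 3
    tumor_radius_mm: float = 10.0
    rim_contrast: float = 0.8
    noise_sd: float = 15.0
    necrotic_fraction: float = 0.25
    smooth_sigma: float = 0.7
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(s < 16 for s in self.grid_shape):
            raise ValueError("grid_shape must be 3 axes, all >= 16")
        if len(self.spacing_mm) != 3 or any(s <= 0 for s in self.spacing_mm):
            raise ValueError("spacing_mm must be 3 positive reals")
        if self.n_lobes < 1:
            raise ValueError("n_lobes must be >= 1")
        if self.tumor_radius_mm <= 0:
            raise ValueError("tumor_radius_mm must be positive")
        if not 0.0 <= self.rim_contrast <= 1.0:
            raise ValueError("rim_contrast must be in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if not 0.0 <= self.necrotic_fraction < 1.0:
            raise ValueError("necrotic_fraction must be in [0, 1)")


@dataclass
class LabeledVolume:
    """A 3D intensity volume with its binary tumor-core ground truth."""

    intensities: np.ndarray
    gt_mask: np.ndarray
    spacing_mm: tuple[float, float, float]
    grade: str
    study_id: str

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        self.gt_mask = np.asarray(self.gt_mask).astype(bool)
        if self.intensities.shape != self.gt_mask.shape:
            raise ValueError("intensities and gt_mask shapes differ")
        if self.intensities.ndim != 3:
            raise ValueError("expected 3D arrays")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("intensities must be finite")
        if not self.gt_mask.any():
            raise ValueError("gt_mask is empty")


def _max_reach_mm(params: PhantomParams) -> float:
    # First lobe: sphere of radius R at the seed point. Extra lobes: centers
    # within a ball of radius R, semi-axes <= 0.6 R  =>  reach <= 1.6 R.
    if params.n_lobes == 1:
        return params.tumor_radius_mm
    return 1.6 * params.tumor_radius_mm


def generate_phantom(params: PhantomParams, study_id: str = "phantom") -> LabeledVolume:
    """Generate one synthetic labeled volume.

    The ground-truth mask is the union of ``n_lobes`` (optionally smoothed)
    ellipsoidal lobes; lobe centers are drawn within a ball of radius
    ``tumor_radius_mm`` around a uniformly chosen interior seed point, which
    yields connected, irregular cores. Intensity is brain-background texture
    plus a ``rim_contrast``-scaled bright shell at the mask boundary, a dimmed
    necrotic interior, and Gaussian noise.

    Raises
    ------
    ValueError
        If the tumor cannot fit inside the grid with a 2-voxel margin.
    """
    rng = np.random.default_rng(derive_seed(params.seed, "phantom", study_id))
    shape = tuple(int(s) for s in params.grid_shape)
    spacing = np.asarray(params.spacing_mm, dtype=float)

    reach_vox = np.ceil(_max_reach_mm(params) / spacing).astype(int) + 2
    lo = reach_vox
    hi = np.asarray(shape) - reach_vox
    if np.any(lo >= hi):
        raise ValueError(
            f"tumor (reach {_max_reach_mm(params):.1f} mm) does not fit in "
            f"grid {shape} with a 2-voxel margin"
        )
    center_vox = np.array([rng.integers(l, h) for l, h in zip(lo, hi)])

    coords = np.stack(
        np.meshgrid(*[np.arange(s) for s in shape], indexing="ij"), axis=-1
    ).astype(float)
    mm = coords * spacing  # physical coordinates of every voxel
    center_mm = center_vox * spacing

    union = np.zeros(shape, dtype=bool)
    radius = params.tumor_radius_mm
    for i in range(params.n_lobes):
        if i == 0:
            lobe_center = center_mm
            semi = np.full(3, radius)
        else:
            # uniform direction, radius ~ U(0,R)^(1/3) * R for uniform-in-ball
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = direction * radius * rng.uniform() ** (1 / 3)
            lobe_center = center_mm + offset
            semi = radius * rng.uniform(0.35, 0.6, size=3)
        d2 = ((mm - lobe_center) / semi) ** 2
        union |= d2.sum(axis=-1) <= 1.0

    if params.smooth_sigma > 0:
        smoothed = ndimage.gaussian_filter(
            union.astype(float), sigma=params.smooth_sigma
        )
        mask = smoothed > 0.5
        if not mask.any():  # pathological tiny lobe; keep the raw union
            mask = union
    else:
        mask = union

    # Guard the fit invariant after smoothing.
    edge = np.zeros(shape, dtype=bool)
    for ax in range(3):
        sl = [slice(None)] * 3
        for idx in (0, 1, -2, -1):
            sl[ax] = idx
            edge[tuple(sl)] = True
    if (mask & edge).any():
        raise ValueError("tumor touches the grid boundary")

    # --- intensity model ---
    grid_center_mm = (np.asarray(shape) - 1) / 2 * spacing
    brain_semi = (np.asarray(shape) - 1) / 2 * spacing * 0.92
    brain = (((mm - grid_center_mm) / brain_semi) ** 2).sum(axis=-1) <= 1.0

    intens = np.where(brain, _BRAIN_BASE, _OUTSIDE_BASE)
    texture = ndimage.gaussian_filter(rng.normal(size=shape), sigma=3.0)
    texture *= _TEXTURE_SD / max(texture.std(), 1e-12)
    intens = intens + np.where(brain, texture, 0.0)

    shell = mask & ~ndimage.binary_erosion(mask, iterations=2)
    interior = mask & ~shell

    dt = ndimage.distance_transform_edt(mask, sampling=spacing)
    if params.necrotic_fraction > 0 and interior.any():
        q = np.quantile(dt[mask], 1.0 - params.necrotic_fraction)
        necrotic = mask & (dt >= q) & interior
    else:
        necrotic = np.zeros(shape, dtype=bool)

    enhancing = interior & ~necrotic
    intens[shell] = _BRAIN_BASE + params.rim_contrast * _RIM_GAIN
    intens[enhancing] = _BRAIN_BASE + params.rim_contrast * _ENHANCING_GAIN
    intens[necrotic] = _NECROTIC_LEVEL

    if params.noise_sd > 0:
        intens = intens + rng.normal(0.0, params.noise_sd, size=shape)
    intens = np.clip(intens, 0.0, None)

    grade = GRADE_HGG if params.rim_contrast >= 0.5 else GRADE_LGG
    return LabeledVolume(
        intensities=intens,
        gt_mask=mask,
        spacing_mm=tuple(float(s) for s in params.spacing_mm),
        grade=grade,
        study_id=study_id,
    )


# ---------------------------------------------------------------------------
# Mock promptable predictor
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MockPredictorParams:
    """Knobs of the mock promptable predictor.

    ``corruption_level`` sets the magnitude of morphological degradation of
    the candidate masks at one prompt; each additional prompt reduces it by
    ``improvement_rate``. ``confidence_calibration`` blends the reported
    confidences between the true-IoU ranking (1.0) and pure noise (0.0).
    ``ambiguity_mode="whole_object"`` makes one single-prompt candidate the
    whole bright-object (brain) support, mimicking the whole-circumference
    failure mode seen with real promptable models on brain MRI.
    """

    corruption_level: float = 3.0
    confidence_calibration: float = 0.25
    ambiguity_mode: str = "none"
    improvement_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("corruption_level", "confidence_calibration", "improvement_rate"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if self.corruption_level < 0 or self.improvement_rate < 0:
            raise ValueError("corruption_level and improvement_rate must be >= 0")
        if not 0.0 <= self.confidence_calibration <= 1.0:
            raise ValueError("confidence_calibration must be in [0, 1]")
        if self.ambiguity_mode not in ("none", "whole_object"):
            raise ValueError("ambiguity_mode must be 'none' or 'whole_object'")


def _image_key(image: np.ndarray) -> str:
    arr = np.ascontiguousarray(image)
    h = hashlib.sha256()
    h.update(str(arr.shape).encode())
    h.update(str(arr.dtype).encode())
    h.update(arr.tobytes())
    return h.hexdigest()


class SliceRegistry:
    """Ground-truth lookup for the mock predictor, keyed by image content.

    The predictor contract only passes the image and the prompts, so the mock
    finds the matching ground truth by hashing the image array. Every slice
    that will be predicted on (including cropped-mode slices) must be
    registered first; the study driver does this automatically.
    """

    def __init__(self) -> None:
        self._store: dict[str, tuple[np.ndarray, float]] = {}

    def register(
        self, image: np.ndarray, gt_mask: np.ndarray, contrast: float | None = None
    ) -> None:
        """Register one slice. ``contrast`` is the lesion-to-surround contrast
        governing corruption strength; prefer a per-study (volume-level)
        estimate so all slices of a study share one difficulty scale — when
        omitted it is estimated from the slice itself."""
        gt = np.asarray(gt_mask).astype(bool)
        if contrast is None:
            contrast = _estimate_contrast(image, gt)
        self._store[_image_key(image)] = (gt, float(contrast))

    def register_sample(self, sample, contrast: float | None = None) -> None:
        self.register(sample.image, sample.gt_mask, contrast)

    def lookup(self, image: np.ndarray) -> tuple[np.ndarray, float]:
        key = _image_key(image)
        if key not in self._store:
            raise KeyError(
                "image not registered with the slice registry; register every "
                "slice before prediction"
            )
        return self._store[key]

    def __len__(self) -> int:
        return len(self._store)


def _estimate_contrast(image: np.ndarray, gt: np.ndarray) -> float:
    """Lesion-to-surround contrast on a 0-1 scale, estimated from the image."""
    channel = np.asarray(image)[..., 0].astype(float)
    ring = ndimage.binary_dilation(gt, iterations=3) & ~gt
    if not ring.any():
        return 0.5
    contrast = (channel[gt].mean() - channel[ring].mean()) / 255.0
    return float(np.clip(contrast, 0.01, 1.0))


def estimate_volume_contrast(vol: LabeledVolume) -> float:
    """Lesion-to-surround contrast of a normalized volume on a 0-1 scale.

    Mean intensity inside the ground-truth core minus the mean in a 3-voxel
    surrounding ring, over the whole 3D mask. One value per study, so every
    slice of a study shares the same predictor difficulty scale.
    """
    channel = vol.intensities.astype(float)
    gt = vol.gt_mask
    ring = ndimage.binary_dilation(gt, iterations=3) & ~gt
    if not ring.any():
        return 0.5
    contrast = (channel[gt].mean() - channel[ring].mean()) / 255.0
    return float(np.clip(contrast, 0.01, 1.0))


# Contrast response of the degradation magnitude: at the reference contrast
# the scale is 1; lower-contrast slices are corrupted proportionally more.
_CONTRAST_REF = 0.25
_SCALE_BOUNDS = (0.5, 3.0)


def _degrade(gt: np.ndarray, magnitude: float, rng: np.random.Generator) -> np.ndarray:
    """Morphological degradation of a ground-truth mask.

    Mixture of translation and dilation/erosion whose strength scales with
    ``magnitude``; draws are taken from ``rng`` in a fixed order so that for
    a fixed generator state the degradation shrinks continuously as
    ``magnitude`` decreases.
    """
    if magnitude <= 0 or not gt.any():
        return gt.copy()
    shift_draw = rng.normal(size=2)
    iter_draw = rng.uniform(0.4, 1.1)
    mode_draw = rng.uniform()

    shift = np.round(shift_draw * magnitude * 0.7).astype(int)
    out = ndimage.shift(gt.astype(np.uint8), shift, order=0, cval=0).astype(bool)

    n_iter = int(round(iter_draw * magnitude))
    if n_iter > 0:
        if mode_draw < 0.5:
            out = ndimage.binary_dilation(out, iterations=n_iter)
        else:
            eroded = ndimage.binary_erosion(out, iterations=n_iter)
            if eroded.any():
                out = eroded
    if not out.any():
        out = gt.copy()
    return out


def _apply_prompt_conditioning(mask: np.ndarray, prompts) -> np.ndarray:
    """Force candidate masks to respect contradicted prompts.

    A foreground prompt falling outside the candidate pulls in a small
    neighborhood; a background prompt falling inside pushes one out. Prompts
    the candidate already agrees with are left alone, so an exact candidate
    stays exact.
    """
    out = mask.copy()
    r = PROMPT_INFLUENCE_RADIUS
    nrow, ncol = out.shape
    for p in prompts:
        inside = bool(out[p.row, p.col])
        fg = p.label == "foreground"
        if fg == inside:
            continue
        r0, r1 = max(0, p.row - r), min(nrow, p.row + r + 1)
        c0, c1 = max(0, p.col - r), min(ncol, p.col + r + 1)
        out[r0:r1, c0:c1] = fg
    return out


def _whole_object_support(image: np.ndarray) -> np.ndarray:
    """Largest bright connected component: the brain, not the tumor."""
    channel = np.asarray(image)[..., 0].astype(float)
    bright = channel > 0.2 * 255.0
    if not bright.any():
        return bright
    labels, n = ndimage.label(bright)
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    return labels == np.argmax(sizes)


class MockPredictor:
    """Callable satisfying the promptable-predictor contract.

    Stateless across calls: all randomness is derived from
    ``(params.seed, image content, candidate index, prompt list)`` via stable
    hashing, so identical inputs give identical outputs.
    """

    def __init__(self, params: MockPredictorParams, registry: SliceRegistry) -> None:
        self.params = params
        self.registry = registry

    def __call__(self, image: np.ndarray, prompts):
        from promptseg.prompt_sim import PredictionTriple, compute_iou

        image = np.asarray(image)
        if image.ndim != 3 or image.shape[-1] != 3:
            raise ValueError("predictor expects a 3-channel 2D image")
        if len(prompts) == 0:
            raise ValueError("empty prompt list")
        nrow, ncol = image.shape[:2]
        for p in prompts:
            if not (0 <= p.row < nrow and 0 <= p.col < ncol):
                raise ValueError(f"prompt ({p.row}, {p.col}) outside image bounds")

        gt, contrast = self.registry.lookup(image)
        n_prompts = len(prompts)
        base = max(
            0.0,
            self.params.corruption_level
            - self.params.improvement_rate * (n_prompts - 1),
        )
        scale = float(np.clip(_CONTRAST_REF / contrast, *_SCALE_BOUNDS))
        magnitude = base * scale

        key = _image_key(image)
        masks = []
        for cand in range(3):
            # Degradation draws are per (image, candidate): as prompts
            # accumulate the same error field shrinks, mimicking a model
            # refining one prediction rather than re-rolling it. Each
            # candidate carries its own severity factor so the three
            # candidates differ in quality and confidence ranking matters.
            rng = np.random.default_rng(
                derive_seed(self.params.seed, "degrade", key, cand)
            )
            severity = rng.uniform(0.5, 1.6)
            m = _degrade(gt, magnitude * severity, rng)
            m = _apply_prompt_conditioning(m, prompts)
            masks.append(m)

        if self.params.ambiguity_mode == "whole_object" and n_prompts == 1:
            masks[2] = _whole_object_support(image)

        ious = np.array([compute_iou(m, gt) for m in masks])
        # average midranks normalized to [0, 1] over the 3 candidates
        order = np.argsort(np.argsort(ious, kind="stable"), kind="stable")
        ranks = order.astype(float)
        for v in np.unique(ious):
            tie = ious == v
            if tie.sum() > 1:
                ranks[tie] = ranks[tie].mean()
        rank_score = ranks / 2.0

        conf_rng = np.random.default_rng(
            derive_seed(
                self.params.seed,
                "confidence",
                key,
                n_prompts,
                tuple((p.row, p.col, p.label) for p in prompts),
            )
        )
        noise = conf_rng.uniform(size=3)
        cal = self.params.confidence_calibration
        confidences = cal * rank_score + (1.0 - cal) * noise
        return PredictionTriple(masks=tuple(masks), confidences=tuple(confidences))


def make_mock_predictor(
    params: MockPredictorParams, gt_lookup: SliceRegistry
) -> MockPredictor:
    """Build a mock predictor backed by a :class:`SliceRegistry`."""
    return MockPredictor(params, gt_lookup)
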