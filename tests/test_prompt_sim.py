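import numpy as np
import pytest

import promptseg as ps
from promptseg.prompt_sim import (
    PredictionTriple,
    PromptPoint,
    compute_iou,
    next_prompt,
    place_initial_point,
    select_mask,
    simulate_slice,
)

from conftest import brute_force_center


class TestIoU:
    def test_identity_and_disjoint(self):
        a = np.zeros((8, 8), bool)
        a[2:5, 2:5] = True
        b = np.zeros((8, 8), bool)
        b[6:8, 6:8] = True
        assert compute_iou(a, a) == 1.0
        assert compute_iou(a, b) == 0.0

    def test_shifted_square(self):
        a = np.zeros((4, 4), bool)
        a[1:3, 0:2] = True
        b = np.zeros((4, 4), bool)
        b[1:3, 1:3] = True  # same 2x2 square shifted one pixel right
        assert compute_iou(a, b) == pytest.approx(2 / 6)

    def test_both_empty_defined_as_one(self):
        e = np.zeros((4, 4), bool)
        assert compute_iou(e, e) == 1.0

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            compute_iou(np.zeros((4, 4), bool), np.zeros((5, 4), bool))


class TestInitialPoint:
    def test_solid_square_center(self):
        gt = np.zeros((9, 9), bool)
        gt[2:7, 2:7] = True
        p = place_initial_point(gt)
        assert (p.row, p.col) == (4, 4)
        assert p.label == "foreground" and p.iteration == 1

    def test_single_pixel(self):
        gt = np.zeros((5, 5), bool)
        gt[3, 1] = True
        p = place_initial_point(gt)
        assert (p.row, p.col) == (3, 1)

    def test_l_shape_matches_brute_force(self):
        gt = np.zeros((12, 12), bool)
        gt[2:10, 2:5] = True
        gt[7:10, 2:10] = True
        p = place_initial_point(gt)
        assert (p.row, p.col) == brute_force_center(gt)[0]

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            place_initial_point(np.zeros((5, 5), bool))


class TestNextPrompt:
    def test_foreground_when_gt_larger(self):
        gt = np.zeros((10, 10), bool)
        gt[2:7, 2:7] = True
        pred = np.zeros((10, 10), bool)
        pred[2:4, 2:4] = True
        p = next_prompt(gt, pred, iteration=2)
        assert p.label == "foreground"
        assert (gt & ~pred)[p.row, p.col]

    def test_background_when_pred_strictly_larger(self):
        gt = np.zeros((10, 10), bool)
        gt[3:6, 3:6] = True
        pred = np.zeros((10, 10), bool)
        pred[2:8, 2:8] = True  # superset of gt
        p = next_prompt(gt, pred, iteration=2)
        assert p.label == "background"
        assert (pred & ~gt)[p.row, p.col]

    def test_area_tie_goes_foreground(self):
        gt = np.zeros((8, 8), bool)
        gt[1:3, 1:3] = True
        pred = np.zeros((8, 8), bool)
        pred[5:7, 5:7] = True  # same area, different place
        assert next_prompt(gt, pred, 2).label == "foreground"

    def test_point_in_largest_component_at_brute_force_center(self):
        gt = np.zeros((16, 16), bool)
        gt[2:8, 2:8] = True    # 36-pixel component
        gt[12:14, 12:14] = True  # 4-pixel component
        pred = np.zeros((16, 16), bool)
        p = next_prompt(gt, pred, 2)
        big = np.zeros_like(gt)
        big[2:8, 2:8] = True
        assert big[p.row, p.col]
        assert (p.row, p.col) == brute_force_center(big)[0]

    def test_equal_masks_rejected(self):
        gt = np.zeros((6, 6), bool)
        gt[2:4, 2:4] = True
        with pytest.raises(ValueError):
            next_prompt(gt, gt.copy(), 2)


def _triple(shape, specs):
    masks = []
    for spec in specs:
        m = np.zeros(shape, bool)
        m[spec] = True
        masks.append(m)
    return masks


class TestSelectMask:
    def test_oracle_vs_suggested_argmax(self):
        gt = np.zeros((8, 8), bool)
        gt[2:6, 2:6] = True
        masks = _triple(
            (8, 8),
            [(slice(0, 2), slice(0, 2)), (slice(2, 6), slice(2, 6)),
             (slice(2, 6), slice(2, 4))],
        )
        triple = PredictionTriple(tuple(masks), (0.9, 0.1, 0.5))
        _, oracle_idx = select_mask(triple, gt, "oracle")
        _, sugg_idx = select_mask(triple, gt, "suggested")
        assert oracle_idx == 1  # exact match has highest calculated IoU
        assert sugg_idx == 0  # highest reported confidence

    def test_identical_masks_tie_break_lowest_index(self):
        gt = np.zeros((6, 6), bool)
        gt[1:3, 1:3] = True
        m = gt.copy()
        triple = PredictionTriple((m, m.copy(), m.copy()), (0.5, 0.5, 0.5))
        for strategy in ("oracle", "suggested"):
            _, idx = select_mask(triple, gt, strategy)
            assert idx == 0
        _, idx = select_mask(triple, gt, "prev_slice", prev_mask=gt)
        assert idx == 0

    def test_prev_slice_similarity(self):
        gt = np.zeros((8, 8), bool)
        gt[2:6, 2:6] = True
        masks = _triple(
            (8, 8),
            [(slice(0, 3), slice(0, 3)), (slice(2, 6), slice(2, 6)),
             (slice(4, 8), slice(4, 8))],
        )
        triple = PredictionTriple(tuple(masks), (0.3, 0.3, 0.3))
        _, idx = select_mask(triple, gt, "prev_slice", prev_mask=masks[2])
        assert idx == 2

    def test_prev_slice_requires_prev_mask(self):
        gt = np.ones((4, 4), bool)
        triple = PredictionTriple((gt, gt, gt), (0.1, 0.2, 0.3))
        with pytest.raises(ValueError):
            select_mask(triple, gt, "prev_slice")


class TestSimulateSlice:
    def test_perfect_predictor_terminates_at_one(
        self, transverse_samples, predictor_factory
    ):
        pred = predictor_factory(transverse_samples, corruption_level=0.0, seed=1)
        for s in transverse_samples[::4]:
            trace = simulate_slice(s, pred, "oracle")
            assert trace.best_iou == 1.0
            assert trace.best_iteration == 1
            assert trace.terminated_early
            assert len(trace.prompts) == 1

    def test_corruption_reaching_zero_gives_perfect_mask(
        self, transverse_samples, predictor_factory
    ):
        # corruption 0.5 with improvement 0.1 hits zero by the 6th prompt
        pred = predictor_factory(
            transverse_samples, corruption_level=0.5, improvement_rate=0.1, seed=2
        )
        for s in transverse_samples[::4]:
            trace = simulate_slice(s, pred, "oracle")
            assert trace.best_iou == 1.0
            assert trace.best_iteration <= 6

    def test_fixed_seed_reproducible(self, transverse_samples, predictor_factory):
        s = transverse_samples[3]
        t1 = simulate_slice(s, predictor_factory(transverse_samples, seed=5), "oracle")
        t2 = simulate_slice(s, predictor_factory(transverse_samples, seed=5), "oracle")
        assert t1.iou_curve.tolist() == t2.iou_curve.tolist()
        assert [(p.row, p.col, p.label) for p in t1.prompts] == [
            (p.row, p.col, p.label) for p in t2.prompts
        ]

    def test_wrong_shape_candidate_names_index(self, transverse_samples):
        s = transverse_samples[0]

        def bad_predictor(image, prompts):
            wrong = np.zeros((3, 3), bool)
            return PredictionTriple((wrong, wrong, wrong), (0.1, 0.2, 0.3))

        with pytest.raises(ValueError, match="candidate 0"):
            simulate_slice(s, bad_predictor, "oracle")

    def test_trace_invariants(self, transverse_samples, predictor_factory):
        """best_iou is the max recorded IoU, best_iteration its first argmax,
        at most nine iterations, and every prompt lies inside the set
        difference that generated it."""
        pred = predictor_factory(transverse_samples, corruption_level=3.0, seed=9)
        for s in transverse_samples[::2]:
            trace = simulate_slice(s, pred, "oracle")
            ious = trace.iou_curve
            assert len(ious) <= 9
            assert trace.best_iou == ious.max()
            assert trace.best_iteration == int(np.argmax(ious)) + 1
            gt = s.gt_mask
            for p in trace.prompts[1:]:
                prev_sel = trace.iterations[p.iteration - 2].selected_mask
                if p.label == "foreground":
                    assert (gt & ~prev_sel)[p.row, p.col]
                else:
                    assert (prev_sel & ~gt)[p.row, p.col]


class TestRunStudy:
    def test_trace_count_equals_tumor_slices(self, predictor_factory):
        vols = [
            ps.generate_phantom(
                ps.PhantomParams(grid_shape=(40, 40, 32), tumor_radius_mm=7, seed=s),
                f"v{s}",
            )
            for s in (21, 22)
        ]
        registry = ps.SliceRegistry()
        pred = ps.make_mock_predictor(ps.MockPredictorParams(seed=1), registry)
        res = ps.run_study(
            vols, pred, strategies=("oracle",), orientations=("transverse",),
            registry=registry,
        )
        expected = sum(
            len(ps.extract_slices(ps.normalize_volume(v), "transverse"))
            for v in vols
        )
        assert len(res.records) == expected

    def test_fully_calibrated_confidences_make_strategies_coincide(
        self, transverse_samples
    ):
        registry = ps.SliceRegistry()
        for s in transverse_samples:
            registry.register_sample(s)
        pred = ps.make_mock_predictor(
            ps.MockPredictorParams(confidence_calibration=1.0, seed=3), registry
        )
        vols = []  # drive via simulate_slice directly on shared samples
        for s in transverse_samples[::3]:
            to = simulate_slice(s, pred, "oracle")
            ts = simulate_slice(s, pred, "suggested")
            assert to.iou_curve.tolist() == ts.iou_curve.tolist()

    def test_aggregate_mean_matches_hand_average(self, predictor_factory):
        vols = [
            ps.generate_phantom(
                ps.PhantomParams(grid_shape=(40, 40, 32), tumor_radius_mm=7, seed=31),
                "h0",
            )
        ]
        registry = ps.SliceRegistry()
        pred = ps.make_mock_predictor(ps.MockPredictorParams(seed=2), registry)
        res = ps.run_study(vols, pred, registry=registry)
        df = res.trace_table()
        agg = res.aggregate()
        row = agg[(agg.grade == "all")].iloc[0]
        assert row.mean_best_iou == pytest.approx(df.best_iou.mean())
        assert row.n_slices == len(df)

    def test_empty_volume_list_rejected(self):
        with pytest.raises(ValueError):
            ps.run_study([], lambda i, p: None)


def test_running_best_iou_is_monotone(transverse_samples, predictor_factory):
    pred = predictor_factory(transverse_samples, corruption_level=3.0, seed=12)
    for s in transverse_samples:
        trace = simulate_slice(s, pred, "oracle")
        running = np.maximum.accumulate(trace.iou_curve)
        assert np.all(np.diff(running) >= 0)


def test_prompt_centers_match_brute_force_on_concave_masks(blob_masks):
    """Corrective-prompt placement equals an independent all-pairs
    distance-map argmax on random concave set differences."""
    from skimage import measure

    masks = blob_masks(25, seed=77)
    rng = np.random.default_rng(4)
    for gt in masks:
        pred = np.roll(gt, (int(rng.integers(-3, 4)), int(rng.integers(-3, 4))),
                       axis=(0, 1))
        if np.array_equal(gt, pred):
            continue
        p = next_prompt(gt, pred, 2)
        fg = gt.sum() >= pred.sum()
        diff = (gt & ~pred) if fg else (pred & ~gt)
        labels = measure.label(diff, connectivity=2)
        sizes = np.bincount(labels.ravel())
        sizes[0] = 0
        # the point lies in a maximal component, at its brute-force center
        own = labels == labels[p.row, p.col]
        assert own.sum() == sizes.max()
        assert (p.row, p.col) == brute_force_center(own)[0]
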