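"""Lead-name objects, recognition, grid completion, and cropping."""

import numpy as np
import pytest

from paperecg import (
    BinaryInkImage,
    LeadNameDetectionError,
    InkObject,
    crop_leads,
    detect_baselines,
    extract_candidate_objects,
    infer_layout,
    infer_missing_names,
    recognise_lead_names,
    remove_baseline_for_ocr,
    remove_grid,
    strip_redaction,
    vertical_anchors,
)
from paperecg.params import DEFAULT_PARAMS
from paperecg.synth import generate_synthetic_ecg
from paperecg.synth.fonts import render_label


def _obj(w, h):
    return InkObject(bbox=(0, 0, w, h), pixel_count=w * h)


class TestObjectFilter:
    from paperecg.leadfind import passes_filters

    @pytest.mark.parametrize(
        "w, h, kept",
        [
            (120, 20, False),   # aspect ratio 6 > 5
            (20, 120, False),   # same, rotated
            (3, 3, False),      # below 5 px
            (30, 4, False),     # one side below 5 px
            (30, 15, True),
            (600, 30, False),   # above 500 px
            (5, 5, True),       # boundary: 5 px sides allowed
            (100, 20, True),    # ratio exactly 5 allowed
        ],
    )
    def test_size_and_aspect_rules(self, w, h, kept):
        from paperecg.leadfind import passes_filters

        assert passes_filters(_obj(w, h)) is kept

    def test_filter_is_order_independent(self, rng):
        from paperecg.leadfind import passes_filters

        objs = [_obj(int(w), int(h)) for w, h in rng.integers(1, 600, size=(50, 2))]
        kept = {o.bbox for o in objs if passes_filters(o)}
        perm = [objs[i] for i in rng.permutation(len(objs))]
        assert {o.bbox for o in perm if passes_filters(o)} == kept

    def test_blank_image_gives_empty_list(self):
        assert extract_candidate_objects(BinaryInkImage(np.zeros((40, 40), bool))) == []

    def test_label_glyphs_arrive_as_one_object(self):
        ink = np.zeros((60, 120), dtype=bool)
        glyph = render_label("avr")
        ink[10:10 + glyph.shape[0], 20:20 + glyph.shape[1]] = glyph
        objs = extract_candidate_objects(BinaryInkImage(ink))
        assert len(objs) == 1
        x0, y0, x1, y1 = objs[0].bbox
        rows, cols = np.nonzero(glyph)
        content = (cols.max() - cols.min() + 1, rows.max() - rows.min() + 1)
        assert (x1 - x0, y1 - y0) >= content


class TestRecognition:
    def test_all_names_found_with_correct_rows(self, truth_3x4, digitised_3x4):
        _, debug = digitised_3x4
        found = {(b.label, b.row) for b in debug["names"].all_boxes() if not b.inferred}
        expected = {(d["label"], d["row"]) for d in truth_3x4.name_boxes}
        assert found == expected

    def test_boxes_overlap_truth_boxes(self, truth_3x4, digitised_3x4):
        _, debug = digitised_3x4
        shift = truth_3x4.redaction_rows
        truth_by_key = {(d["label"], d["row"]): d["bbox"] for d in truth_3x4.name_boxes}
        for b in debug["names"].all_boxes():
            tx0, ty0, tx1, ty1 = truth_by_key[(b.label, b.row)]
            ty0, ty1 = ty0 - shift, ty1 - shift
            x0, y0, x1, y1 = b.bbox
            ix = max(0, min(x1, tx1) - max(x0, tx0))
            iy = max(0, min(y1, ty1) - max(y0, ty0))
            inter = ix * iy
            union = (x1 - x0) * (y1 - y0) + (tx1 - tx0) * (ty1 - ty0) - inter
            assert inter / union >= 0.5

    def test_precision_of_recognised_names(self, truth_3x4, digitised_3x4):
        # false labels are worse than missing ones: precision >= 0.95
        _, debug = digitised_3x4
        boxes = [b for b in debug["names"].all_boxes() if not b.inferred]
        truth = {(d["label"], d["row"]) for d in truth_3x4.name_boxes}
        correct = sum((b.label, b.row) in truth for b in boxes)
        assert boxes and correct / len(boxes) >= 0.95

    def test_empty_object_list_yields_no_names(self, recogniser, truth_3x4):
        bin_img = remove_grid(strip_redaction(truth_3x4.image))
        layout = vertical_anchors(
            infer_layout(detect_baselines(bin_img)), bin_img.height_px
        )
        assert recognise_lead_names([], bin_img, recogniser, layout) == []

    def test_noise_blob_is_not_a_lead_name(self, recogniser, rng):
        patch = rng.random((25, 60)) < 0.5
        label, conf = recogniser.recognise(patch)
        assert conf < DEFAULT_PARAMS.confidence_threshold

    def test_recogniser_failure_is_not_fatal(self, truth_3x4):
        class Broken:
            def recognise(self, patch):
                raise RuntimeError("boom")

        bin_img = remove_grid(strip_redaction(truth_3x4.image))
        layout = vertical_anchors(
            infer_layout(detect_baselines(bin_img)), bin_img.height_px
        )
        objs = extract_candidate_objects(bin_img)
        assert recognise_lead_names(objs, bin_img, Broken(), layout) == []


class TestBaselineRemovalForOcr:
    def test_clears_rows_and_keeps_original(self, truth_3x4):
        bin_img = remove_grid(strip_redaction(truth_3x4.image))
        layout = infer_layout(detect_baselines(bin_img))
        before = bin_img.ink.copy()
        cleared = remove_baseline_for_ocr(bin_img, layout)
        np.testing.assert_array_equal(bin_img.ink, before)  # original untouched
        for b in layout.baselines:
            assert not cleared.ink[b.y_px - 1: b.y_px + 2].any()

    def test_image_without_baseline_ink_unchanged(self):
        ink = np.zeros((50, 300), dtype=bool)
        ink[10, 5:30] = True
        from paperecg.layout import Baseline, LayoutModel

        layout = LayoutModel([Baseline(40, 0, 300, 300)])
        out = remove_baseline_for_ocr(BinaryInkImage(ink), layout)
        np.testing.assert_array_equal(out.ink, ink)

    def test_names_on_baseline_need_removal(self, recogniser):
        truth = generate_synthetic_ecg(
            seed=4, layout_kind="3x4_rhythm", noise_density=0.0, names_on_baseline=True
        )
        bin_img = remove_grid(strip_redaction(truth.image))
        layout = vertical_anchors(
            infer_layout(detect_baselines(bin_img)), bin_img.height_px
        )
        before = recognise_lead_names(
            extract_candidate_objects(bin_img), bin_img, recogniser, layout
        )
        cleared = remove_baseline_for_ocr(bin_img, layout)
        after = recognise_lead_names(
            extract_candidate_objects(cleared), cleared, recogniser, layout
        )
        assert before == []
        assert len(after) >= 4


class TestInferMissingNames:
    def _grid_parts(self, truth, digitised):
        _, debug = digitised
        layout = debug["layout"]
        found = [b for b in debug["names"].all_boxes() if not b.inferred]
        return layout, found

    def test_all_found_is_identity(self, truth_3x4, digitised_3x4):
        layout, found = self._grid_parts(truth_3x4, digitised_3x4)
        grid = infer_missing_names(found, layout)
        assert all(not b.inferred for b in grid.all_boxes())
        assert len(grid.all_boxes()) == 13

    def test_missing_name_is_placed_from_spacing(self, truth_3x4, digitised_3x4):
        layout, found = self._grid_parts(truth_3x4, digitised_3x4)
        kept = [b for b in found if b.label != "v4"]
        grid = infer_missing_names(kept, layout)
        v4 = next(b for b in grid.rows[0] if b.label == "v4")
        assert v4.inferred
        truth_box = next(
            d["bbox"] for d in truth_3x4.name_boxes if d["label"] == "v4"
        )
        assert abs(v4.bbox[0] - truth_box[0]) <= 10

    def test_zero_names_raises(self, truth_3x4, digitised_3x4):
        layout, _ = self._grid_parts(truth_3x4, digitised_3x4)
        with pytest.raises(LeadNameDetectionError):
            infer_missing_names([], layout)


class TestCropLeads:
    def test_crops_cover_own_lead_ink(self, truth_3x4, digitised_3x4):
        _, debug = digitised_3x4
        shift = truth_3x4.redaction_rows
        crop_by = {(c.row, c.col): c for c in debug["crops"]}
        for (row, col), (rr, cc) in truth_3x4.lead_ink_px.items():
            c = crop_by[(row, col)]
            inside = (
                (rr - shift >= c.y_offset_global)
                & (rr - shift < c.y_offset_global + c.height_px)
                & (cc >= c.x_offset_global)
                & (cc < c.x_offset_global + c.width_px)
            )
            assert inside.mean() >= 0.99

    def test_rows_tile_without_horizontal_overlap(self, digitised_3x4):
        _, debug = digitised_3x4
        by_row = {}
        for c in debug["crops"]:
            by_row.setdefault(c.row, []).append(c)
        for crops in by_row.values():
            crops.sort(key=lambda c: c.x_offset_global)
            for a, b in zip(crops, crops[1:]):
                assert a.x_offset_global + a.width_px <= b.x_offset_global + 1

    def test_each_lead_exactly_once(self, digitised_3x4):
        record, debug = digitised_3x4
        labels = [c.label for c in debug["crops"] if c.row != 3]
        assert sorted(labels) == sorted(set(labels))
        assert len(labels) == 12

    def test_crop_height_is_1p4_of_row_distance(self, digitised_3x4):
        _, debug = digitised_3x4
        layout = debug["layout"]
        ys = [b.y_px for b in layout.baselines]
        for c in debug["crops"]:
            d = min(
                abs(ys[c.row] - ys[j]) for j in range(len(ys)) if j != c.row
            )
            assert abs(c.height_px - 1.4 * d) <= 2

    def test_single_name_rows_run_to_the_margin(self, truth_3x1, recogniser):
        from paperecg import digitise_image

        _, debug = digitise_image(
            truth_3x1.image, recogniser=recogniser, return_debug=True
        )
        width = truth_3x1.image.width_px
        for c in debug["crops"]:
            assert c.x_offset_global + c.width_px == width
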