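"""End-to-end digitisation: scan image in, calibrated 12-lead record out."""

from __future__ import annotations

import logging
from pathlib import Path

from .extract import assemble_record, calibrate, collapse_to_series, isolate_trace
from .image_io import RasterImage, load_image
from .layout import LayoutModel, detect_baselines, infer_layout, vertical_anchors
from .leadfind import (
    TemplateRecogniser,
    crop_leads,
    extract_candidate_objects,
    infer_missing_names,
    recognise_lead_names,
    remove_baseline_for_ocr,
)
from .params import DEFAULT_PARAMS, PipelineParams
from .preprocess import remove_grid, strip_redaction
from .signals import ECGRecord

log = logging.getLogger(__name__)

_DEFAULT_RECOGNISER: TemplateRecogniser | None = None


def _default_recogniser() -> TemplateRecogniser:
    global _DEFAULT_RECOGNISER
    if _DEFAULT_RECOGNISER is None:
        _DEFAULT_RECOGNISER = TemplateRecogniser()
    return _DEFAULT_RECOGNISER


def digitise_image(
    image: RasterImage | str | Path,
    params: PipelineParams = DEFAULT_PARAMS,
    recogniser=None,
    return_debug: bool = False,
):
    """Run the full pipeline on a scanned 12-lead ECG.

    Steps: strip the redaction header; remove the grid and binarise;
    detect baselines (constrained Hough); locate lead names (text objects
    on a baseline-cleared working copy, template recognition); infer the
    layout and fill missing names from spacing; crop each lead; isolate
    and collapse its trace; calibrate against the rhythm/longest strip.

    Returns the :class:`ECGRecord` (or ``(record, debug)`` with the layout
    model, name grid and crops when ``return_debug`` is set).
    """
    if isinstance(image, (str, Path)):
        image = load_image(image)
    recogniser = recogniser or _default_recogniser()

    image = strip_redaction(image, params)
    bin_img = remove_grid(image, params)
    baselines = detect_baselines(bin_img, params)

    provisional = vertical_anchors(
        infer_layout(baselines), bin_img.height_px, params
    )
    working = remove_baseline_for_ocr(bin_img, provisional, params)
    objects = extract_candidate_objects(working, params)
    named = recognise_lead_names(objects, working, recogniser, provisional, params)

    names_per_row = [0] * len(baselines)
    for b in named:
        names_per_row[b.row] += 1
    layout = vertical_anchors(
        infer_layout(baselines, names_per_row), bin_img.height_px, params
    )
    for b in named:  # re-check band membership under the final layout
        b.row = min(b.row, layout.n_rows - 1)
    grid = infer_missing_names(named, layout)
    crops = crop_leads(bin_img, layout, grid, params)

    series = []
    for crop in crops:
        cleaned = isolate_trace(crop, params)
        series.append((crop, collapse_to_series(cleaned)))
    # Time calibration from the rhythm (or longest) strip.  Its row's column
    # count converts strip width to the full-record x-axis width: a lone
    # full-width strip spans the whole 10 s, but the longest strip of a
    # column-split page (e.g. 6x2) spans only 10 s / n_cols.
    longest_crop, longest = max(series, key=lambda cs: cs[1].width_px)
    rhythm_width = longest.width_px * max(1, len(grid.rows[longest_crop.row]))

    rhythm_sig = None
    lead_sigs = []
    rhythm_row = (
        layout.n_rows - 1 if layout.layout_kind == "3x4_rhythm" else None
    )
    for crop, ser in series:
        sig = calibrate(ser, rhythm_width, params, col=crop.col)
        if rhythm_row is not None and crop.row == rhythm_row:
            rhythm_sig = sig
        else:
            lead_sigs.append(sig)

    record = assemble_record(
        lead_sigs,
        layout,
        rhythm=rhythm_sig,
        calibration={
            "rhythm_width_px": rhythm_width,
            "time_res_ms_per_px": params.record_duration_s * 1000.0 / rhythm_width,
            "vt_ratio_mv_per_ms": params.vt_ratio_mv_per_ms,
        },
        provenance={
            "layout_kind": layout.layout_kind,
            "inferred_names": [b.label for b in grid.all_boxes() if b.inferred],
        },
    )
    if return_debug:
        return record, {"layout": layout, "names": grid, "crops": crops}
    return record
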