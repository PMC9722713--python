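"""Trace isolation, series collapse, and voltage/time calibration.

Inside each crop the signal of interest is the largest connected ink
object after a horizontal dilation bridges drawing gaps; everything else
(salt-and-pepper specks, encroaching QRS tips from neighbouring rows) is
artefact.  The surviving ink is collapsed to one value per column (the
median ink row), then calibrated: the rhythm (or longest) strip is by
convention 10 s wide, which fixes the time resolution, and the fixed
0.0025 mV/ms voltage-time ratio of 25 mm/s / 10 mm/mV paper fixes the
voltage resolution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import CalibrationError, EmptyLeadError, IncompleteRecordError
from .layout import LayoutModel
from .leadfind import LeadCrop
from .params import DEFAULT_PARAMS, PipelineParams
from .signals import LAYOUT_LEADS, LAYOUT_N_COLS, DigitalSignal, ECGRecord


@dataclass
class PixelSeries:
    """Per-column trace: one (lower-)median ink row per occupied column.

    ``x_px`` are strictly increasing crop-local column indices; columns
    with no ink are absent and are filled by interpolation at calibration.
    """

    x_px: np.ndarray
    y_px: np.ndarray
    baseline_y_px: int
    lead: str = ""

    @property
    def width_px(self) -> int:
        """Pixel span of the signal along the x-axis (inclusive)."""
        return int(self.x_px[-1] - self.x_px[0] + 1)


def isolate_trace(crop: LeadCrop, params: PipelineParams = DEFAULT_PARAMS) -> LeadCrop:
    """Keep only the largest ink object; drop noise and neighbour fragments.

    A horizontal 1xN dilation first connects discontinuities in the trace;
    components are then labelled on the dilated image, sized by their
    pre-dilation ink count, and only ink under the largest component is
    retained.  Ties go to the larger count, then the leftmost bounding box.
    """
    if not crop.ink.any():
        raise EmptyLeadError(crop.label)
    selem = np.ones((1, params.trace_dilate_len_px), dtype=bool)
    dilated = ndimage.binary_dilation(crop.ink, structure=selem)
    # 8-connectivity: steep trace segments are corner-connected staircases
    labels, n = ndimage.label(dilated, structure=np.ones((3, 3), dtype=bool))
    counts = np.bincount(labels[crop.ink], minlength=n + 1)
    counts[0] = 0
    best = int(np.argmax(counts))
    ties = np.nonzero(counts == counts[best])[0]
    if ties.size > 1:
        slices = ndimage.find_objects(labels)
        best = int(min(ties, key=lambda i: slices[i - 1][1].start))
    kept = crop.ink & (labels == best)
    return LeadCrop(
        label=crop.label,
        ink=kept,
        baseline_y_local=crop.baseline_y_local,
        x_offset_global=crop.x_offset_global,
        y_offset_global=crop.y_offset_global,
        row=crop.row,
        col=crop.col,
        inferred_name=crop.inferred_name,
    )


def collapse_to_series(crop: LeadCrop) -> PixelSeries:
    """Collapse a cleaned crop to one y per column (lower median of ink rows)."""
    ys, xs = np.nonzero(crop.ink)
    if xs.size == 0:
        raise EmptyLeadError(crop.label)
    order = np.lexsort((ys, xs))
    xs_s, ys_s = xs[order], ys[order]
    cols, starts, counts = np.unique(xs_s, return_index=True, return_counts=True)
    med_idx = starts + (counts - 1) // 2  # lower median keeps y on the pixel lattice
    return PixelSeries(
        x_px=cols.astype(np.int64),
        y_px=ys_s[med_idx].astype(np.int64),
        baseline_y_px=crop.baseline_y_local,
        lead=crop.label,
    )


def calibrate(
    series: PixelSeries,
    rhythm_width_px: int,
    params: PipelineParams = DEFAULT_PARAMS,
    col: int = 0,
) -> DigitalSignal:
    """Convert a pixel series to millivolts and milliseconds.

    ``rhythm_width_px`` is the x-axis pixel span of the rhythm (or longest)
    strip, which spans ``record_duration_s`` by convention; hence
    ``time_res = 10 000 ms / rhythm_width_px`` and ``volt_res = time_res x
    0.0025 mV/ms``.  Ink-free columns are filled by linear interpolation,
    and voltage is measured upward from the row baseline (y grows downward).
    """
    if rhythm_width_px <= 0:
        raise CalibrationError(f"non-positive rhythm width: {rhythm_width_px}")
    time_res = params.record_duration_s * 1000.0 / rhythm_width_px
    volt_res = time_res * params.vt_ratio_mv_per_ms
    cols = np.arange(series.x_px[0], series.x_px[-1] + 1)
    y_full = np.interp(cols, series.x_px, series.y_px.astype(np.float64))
    t_ms = (cols - cols[0]) * time_res
    v_mv = (series.baseline_y_px - y_full) * volt_res
    return DigitalSignal(
        lead=series.lead,
        t_ms=t_ms,
        v_mv=v_mv,
        time_res_ms_per_px=time_res,
        volt_res_mv_per_px=volt_res,
        col=col,
    )


def assemble_record(
    signals: list[DigitalSignal],
    layout: LayoutModel,
    rhythm: DigitalSignal | None = None,
    calibration: dict | None = None,
    provenance: dict | None = None,
) -> ECGRecord:
    """Order the leads and place each at its page column's time offset.

    On multi-column pages column k starts at k x duration/n_cols (2.5 s per
    column on a 3x4 page).  Missing or duplicated labels raise
    ``IncompleteRecordError``.
    """
    labels = [s.lead for s in signals]
    if len(set(labels)) != len(labels):
        dupes = sorted({l for l in labels if labels.count(l) > 1})
        raise IncompleteRecordError(f"incomplete record: duplicate lead(s) {dupes}")
    n_cols = LAYOUT_N_COLS.get(layout.layout_kind, 1)
    seg_ms = DEFAULT_PARAMS.record_duration_s * 1000.0 / n_cols
    placed = {s.lead: s.shifted(s.col * seg_ms) for s in signals}
    expected = LAYOUT_LEADS.get(layout.layout_kind)
    if expected is not None and set(placed) != set(expected):
        missing = sorted(set(expected) - set(placed))
        raise IncompleteRecordError(f"incomplete record: missing lead(s) {missing}")
    return ECGRecord(
        signals=placed,
        layout_kind=layout.layout_kind,
        rhythm=rhythm,
        calibration=calibration or {},
        provenance=provenance or {},
    )
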