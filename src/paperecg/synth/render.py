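"""Rasterise 12-lead waveforms into a ground-truthed synthetic paper ECG.

The renderer emulates the features of a 250 dpi hospital scan that the
digitisation pipeline must cope with: a black redaction header, a pale
red/pink millimetre grid, dark 1-2 px signal polylines at 25 mm/s and
10 mm/mV, printed lead-name labels at row/column starts, and sparse
salt-and-pepper noise.  Everything is seeded and every piece of ground
truth (waveforms, baseline rows, name boxes, ink/grid masks, per-lead ink
coordinates) is recorded so round-trip tests need no external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import line as draw_line

from ..image_io import RasterImage
from ..signals import DigitalSignal
from .fonts import render_label
from .waveforms import WaveParams, generate_waveforms

#: Lead label grid per layout; inner lists are page rows, left to right.
GRID_LABELS: dict[str, list[list[str]]] = {
    "3x4_rhythm": [
        ["I", "avr", "v1", "v4"],
        ["II", "avl", "v2", "v5"],
        ["III", "avf", "v3", "v6"],
        ["II"],  # rhythm strip
    ],
    "3x4": [
        ["I", "avr", "v1", "v4"],
        ["II", "avl", "v2", "v5"],
        ["III", "avf", "v3", "v6"],
    ],
    "6x2": [["I", "v1"], ["II", "v2"], ["III", "v3"], ["avr", "v4"], ["avl", "v5"], ["avf", "v6"]],
    "12x1": [["I"], ["II"], ["III"], ["avr"], ["avl"], ["avf"],
             ["v1"], ["v2"], ["v3"], ["v4"], ["v5"], ["v6"]],
    "3x1": [["I"], ["II"], ["v1"]],
}


@dataclass(frozen=True)
class RenderSpec:
    """Geometry and appearance of the rendered page.

    ``overlap_factor`` multiplies drawn amplitudes by (1 + overlap_factor);
    at 0 the row pitch guarantees that no row's ink enters a neighbouring
    row's 0.7x anchor band.  ``names_on_baseline`` drops each label onto its
    row's baseline so that label and trace merge into one ink component (the
    failure mode that baseline removal before OCR repairs).
    """

    layout_kind: str = "3x4_rhythm"
    dpi: float = 250.0
    paper_speed_mm_s: float = 25.0
    gain_mm_mv: float = 10.0
    grid_spacing_mm: float = 1.0
    grid_rgb: tuple[float, float, float] = (1.0, 0.93, 0.93)
    font_face: str = "block"
    font_scale: int = 4
    redaction_band_px: int = 100
    noise_density: float = 5e-4
    overlap_factor: float = 0.0
    row_pitch_mm: float = 40.0
    margin_px: int = 60
    name_allowance_px: int = 90
    name_above_baseline_px: int = 40
    names_on_baseline: bool = False
    trace_thickness_px: int = 2
    seed: int = 0

    @property
    def px_per_mm(self) -> float:
        return self.dpi / 25.4

    @property
    def px_per_ms(self) -> float:
        return self.paper_speed_mm_s * self.px_per_mm / 1000.0


@dataclass
class SyntheticTruth:
    """A rendered page plus everything needed to grade a digitisation."""

    image: RasterImage
    waveforms: dict[str, DigitalSignal]          # full-duration truth per lead
    baseline_ys: list[int]                       # per row, image coordinates
    name_boxes: list[dict]                       # label, row, col, bbox (x0,y0,x1,y1)
    ink_mask: np.ndarray                         # traces + labels
    grid_mask: np.ndarray                        # gridlines not under ink
    lead_ink_px: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]]  # (row,col)->(rows,cols)
    row_leads: list[list[str]]
    redaction_rows: int
    layout_kind: str
    spec: RenderSpec = field(repr=False, default=None)
    rhythm_row: int | None = None


def _draw_polyline(canvas_ink: np.ndarray, xs: np.ndarray, ys: np.ndarray, thickness: int) -> tuple[np.ndarray, np.ndarray]:
    """Mark a polyline (with vertical thickness) on a boolean canvas.

    Returns the (rows, cols) of all marked pixels.
    """
    H, W = canvas_ink.shape
    rr_all, cc_all = [], []
    for i in range(len(xs) - 1):
        rr, cc = draw_line(ys[i], xs[i], ys[i + 1], xs[i + 1])
        rr_all.append(rr)
        cc_all.append(cc)
    rr = np.concatenate(rr_all) if rr_all else np.array([], dtype=int)
    cc = np.concatenate(cc_all) if cc_all else np.array([], dtype=int)
    thick_rr = [rr + k for k in range(thickness)]
    rr = np.concatenate(thick_rr)
    cc = np.tile(cc, thickness)
    keep = (rr >= 0) & (rr < H) & (cc >= 0) & (cc < W)
    rr, cc = rr[keep], cc[keep]
    canvas_ink[rr, cc] = True
    return rr, cc


def render(truth_signals: dict[str, DigitalSignal], spec: RenderSpec) -> SyntheticTruth:
    """Rasterise the given 12-lead waveforms according to ``spec``."""
    if spec.layout_kind not in GRID_LABELS:
        raise ValueError(f"unknown layout kind: {spec.layout_kind!r}")
    grid_rows = GRID_LABELS[spec.layout_kind]
    any_lead = next(iter(truth_signals.values()))
    duration_ms = any_lead.t_ms[-1] + any_lead.time_res_ms_per_px

    pitch_px = int(round(spec.row_pitch_mm * spec.px_per_mm))
    # Column pitch: widest row decides the page width.
    max_cols = max(len(r) for r in grid_rows)
    seg_ms = duration_ms / max_cols
    seg_px = int(round(seg_ms * spec.px_per_ms))
    col_pitch = spec.name_allowance_px + seg_px
    full_px = int(round(duration_ms * spec.px_per_ms))
    body_w = max(max_cols * col_pitch, spec.name_allowance_px + full_px)
    W = spec.margin_px + body_w + spec.margin_px
    top_clear = int(round(0.75 * pitch_px))
    y_first = spec.redaction_band_px + top_clear
    H = y_first + (len(grid_rows) - 1) * pitch_px + top_clear
    glyph_h = 7 * spec.font_scale
    if (
        W < 2 * spec.name_allowance_px
        or H <= spec.redaction_band_px
        or pitch_px <= spec.name_above_baseline_px + glyph_h
        or seg_px < 2
    ):
        raise ValueError("page too small for layout")

    page = np.ones((H, W, 3), dtype=np.float32)
    ink = np.zeros((H, W), dtype=bool)

    # --- millimetre grid (below the redaction band) ---
    grid_mask = np.zeros((H, W), dtype=bool)
    step = spec.grid_spacing_mm * spec.px_per_mm
    rows_idx = np.unique(np.rint(np.arange(spec.redaction_band_px, H, step)).astype(int))
    cols_idx = np.unique(np.rint(np.arange(0, W, step)).astype(int))
    grid_mask[rows_idx[rows_idx < H], :] = True
    grid_mask[:, cols_idx[cols_idx < W]] = True
    grid_mask[: spec.redaction_band_px, :] = False
    page[grid_mask] = np.asarray(spec.grid_rgb, dtype=np.float32)

    amp_mult = 1.0 + spec.overlap_factor
    gain_px_per_mv = spec.gain_mm_mv * spec.px_per_mm

    baseline_ys: list[int] = []
    name_boxes: list[dict] = []
    lead_ink: dict[tuple[int, int], tuple[np.ndarray, np.ndarray]] = {}
    rhythm_row = None

    for r, labels in enumerate(grid_rows):
        y_base = y_first + r * pitch_px
        baseline_ys.append(y_base)
        n_cols = len(labels)
        row_seg_ms = duration_ms / n_cols
        if spec.layout_kind == "3x4_rhythm" and r == len(grid_rows) - 1:
            rhythm_row = r
        for c, label in enumerate(labels):
            x_cell = spec.margin_px + c * col_pitch
            # --- lead name ---
            glyph = render_label(label, spec.font_face, spec.font_scale)
            gh, gw = glyph.shape
            gx0 = x_cell + 4
            if spec.names_on_baseline:
                gy1 = y_base + 2  # glyph bottom overlaps the trace rows
            else:
                gy1 = y_base - spec.name_above_baseline_px
            gy0 = gy1 - gh
            sub = page[gy0:gy1, gx0:gx0 + gw]
            sub[glyph] = 0.0
            ink[gy0:gy1, gx0:gx0 + gw] |= glyph
            name_boxes.append(
                {"label": label, "row": r, "col": c, "bbox": (gx0, gy0, gx0 + gw, gy1)}
            )
            # --- trace ---
            sig = truth_signals[label]
            t0, t1 = c * row_seg_ms, (c + 1) * row_seg_ms
            sel = (sig.t_ms >= t0) & (sig.t_ms < t1)
            t_seg = sig.t_ms[sel]
            v_seg = sig.v_mv[sel] * amp_mult
            x_start = x_cell + spec.name_allowance_px
            xs = x_start + np.rint((t_seg - t0) * spec.px_per_ms).astype(int)
            ys = y_base - np.rint(v_seg * gain_px_per_mv).astype(int)
            rr, cc = _draw_polyline(ink, xs, ys, spec.trace_thickness_px)
            page[rr, cc] = 0.05  # near-black signal ink
            lead_ink[(r, c)] = (rr, cc)
            if spec.names_on_baseline:
                # isoelectric run-in under the label joining it to the
                # trace, so label and trace form one oversized component
                crr, ccc = _draw_polyline(
                    ink,
                    np.array([max(0, gx0 - 2), x_start]),
                    np.array([y_base, y_base]),
                    spec.trace_thickness_px,
                )
                page[crr, ccc] = 0.05

    grid_mask &= ~ink

    # --- redaction band ---
    if spec.redaction_band_px > 0:
        page[: spec.redaction_band_px, :] = 0.0

    # --- salt-and-pepper noise ---
    if spec.noise_density > 0:
        rng = np.random.default_rng(spec.seed + 987654321)
        area = (H - spec.redaction_band_px) * W
        n_noise = int(spec.noise_density * area)
        nr = rng.integers(spec.redaction_band_px, H, size=n_noise)
        nc = rng.integers(0, W, size=n_noise)
        salt = rng.random(n_noise) < 0.5
        page[nr[salt], nc[salt]] = 1.0
        page[nr[~salt], nc[~salt]] = 0.05
        ink[nr[salt], nc[salt]] = False
        grid_mask[nr, nc] = False

    return SyntheticTruth(
        image=RasterImage(page, dpi=spec.dpi),
        waveforms=truth_signals,
        baseline_ys=baseline_ys,
        name_boxes=name_boxes,
        ink_mask=ink,
        grid_mask=grid_mask,
        lead_ink_px=lead_ink,
        row_leads=[list(r) for r in grid_rows],
        redaction_rows=spec.redaction_band_px,
        layout_kind=spec.layout_kind,
        spec=spec,
        rhythm_row=rhythm_row,
    )


def generate_synthetic_ecg(
    seed: int = 0,
    layout_kind: str = "3x4_rhythm",
    wave_params: WaveParams | None = None,
    **spec_overrides,
) -> SyntheticTruth:
    """Convenience wrapper: seeded waveforms + rendered page in one call."""
    wp = wave_params or WaveParams(seed=seed)
    spec = RenderSpec(layout_kind=layout_kind, seed=seed, **spec_overrides)
    return render(generate_waveforms(wp), spec)
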