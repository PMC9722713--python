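"""Lead-name localisation and per-lead cropping.

Printed lead names (I, II, III, avr, avl, avf, v1..v6) are the horizontal
anchors of the method: each lead's crop runs from the end of its own name
to the start of the next name in the row.  Candidate text objects are
connected components of the ink image after a dilation-then-erosion pass,
filtered by size and aspect ratio; a pluggable recogniser scores each
candidate against the 12-string vocabulary.  Names that the recogniser
misses are reconstructed from the spacing of the names it found.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.transform import resize

from .errors import AnchorGeometryError, LeadNameDetectionError
from .image_io import BinaryInkImage
from .layout import LayoutModel
from .params import DEFAULT_PARAMS, PipelineParams
from .synth.fonts import LEAD_VOCABULARY, render_label

log = logging.getLogger(__name__)

#: Expected label grid per layout kind (mirrors how pages are printed).
EXPECTED_GRIDS: dict[str, list[list[str]]] = {
    "3x4_rhythm": [
        ["I", "avr", "v1", "v4"],
        ["II", "avl", "v2", "v5"],
        ["III", "avf", "v3", "v6"],
        ["II"],
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
class InkObject:
    """A connected ink component candidate, half-open bbox (x0, y0, x1, y1)."""

    bbox: tuple[int, int, int, int]
    pixel_count: int

    @property
    def width_px(self) -> int:
        return self.bbox[2] - self.bbox[0]

    @property
    def height_px(self) -> int:
        return self.bbox[3] - self.bbox[1]

    @property
    def centre(self) -> tuple[float, float]:
        x0, y0, x1, y1 = self.bbox
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class NamedBox:
    """A recognised (or inferred) lead-name box."""

    label: str
    bbox: tuple[int, int, int, int]
    confidence: float
    row: int = -1
    col: int = -1
    inferred: bool = False


@dataclass
class NameGrid:
    """Complete per-row name boxes, aligned with the layout's rows."""

    rows: list[list[NamedBox]]
    layout_kind: str

    def all_boxes(self) -> list[NamedBox]:
        return [b for row in self.rows for b in row]


def passes_filters(obj: InkObject, params: PipelineParams = DEFAULT_PARAMS) -> bool:
    """Size/aspect object filter: rejects traces, specks and page furniture."""
    w, h = obj.width_px, obj.height_px
    if w < params.obj_min_px or h < params.obj_min_px:
        return False
    if w > params.obj_max_px or h > params.obj_max_px:
        return False
    if max(w, h) / min(w, h) > params.wh_ratio_max:
        return False
    return True


def extract_candidate_objects(
    bin_img: BinaryInkImage, params: PipelineParams = DEFAULT_PARAMS
) -> list[InkObject]:
    """Connected components after dilation-then-erosion, size/aspect filtered.

    The closing pass fuses the glyphs of one label into a single component
    so whole lead names are detected rather than individual letters.
    """
    selem = np.ones((params.close_selem_px, params.close_selem_px), dtype=bool)
    closed = ndimage.binary_erosion(
        ndimage.binary_dilation(bin_img.ink, structure=selem), structure=selem
    )
    # 8-connectivity: diagonal glyph strokes are corner-connected staircases
    labels, n = ndimage.label(closed, structure=np.ones((3, 3), dtype=bool))
    raw: list[InkObject] = []
    for i, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        count = int((labels[sl] == i).sum())
        raw.append(InkObject(bbox=(x0, y0, x1, y1), pixel_count=count))
    merged = _group_words(raw, params.glyph_merge_gap_px)
    return [o for o in merged if passes_filters(o, params)]


def _group_words(objects: list[InkObject], max_gap: int) -> list[InkObject]:
    """Fuse letter components into words.

    Two components belong to the same word when their boxes are separated
    horizontally by at most ``max_gap`` pixels and overlap vertically by at
    least half the smaller height (thin erosion bridges between glyphs do
    not survive the closing pass, so letters of one label arrive as
    separate components).
    """
    n = len(objects)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    order = sorted(range(n), key=lambda i: objects[i].bbox[0])
    for ai in range(n):
        a = objects[order[ai]]
        for bi in range(ai + 1, n):
            b = objects[order[bi]]
            gap = b.bbox[0] - a.bbox[2]
            if gap > max_gap:
                break  # objects sorted by x0; no later object can be closer
            overlap = min(a.bbox[3], b.bbox[3]) - max(a.bbox[1], b.bbox[1])
            min_h = min(a.bbox[3] - a.bbox[1], b.bbox[3] - b.bbox[1])
            if overlap >= 0.5 * min_h:
                ra, rb = find(order[ai]), find(order[bi])
                if ra != rb:
                    parent[rb] = ra
    groups: dict[int, list[InkObject]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(objects[i])
    out = []
    for members in groups.values():
        x0 = min(m.bbox[0] for m in members)
        y0 = min(m.bbox[1] for m in members)
        x1 = max(m.bbox[2] for m in members)
        y1 = max(m.bbox[3] for m in members)
        out.append(InkObject(bbox=(x0, y0, x1, y1),
                             pixel_count=sum(m.pixel_count for m in members)))
    return sorted(out, key=lambda o: (o.bbox[1], o.bbox[0]))


class TemplateRecogniser:
    """Normalised cross-correlation matcher against rendered label templates.

    The contract any recogniser must satisfy: ``recognise(patch)`` takes a
    boolean image patch and returns ``(best_vocabulary_match, confidence)``
    with confidence in [0, 1] (label may be None).  This default is fully
    deterministic and needs no model download; an external OCR engine can
    be dropped in behind the same contract.
    """

    def __init__(
        self,
        faces: tuple[str, ...] = ("block", "sans"),
        scale: int = 4,
        vocabulary: tuple[str, ...] = LEAD_VOCABULARY,
    ):
        self.vocabulary = vocabulary
        self.faces = faces
        self.templates: list[tuple[str, np.ndarray]] = []
        for label in vocabulary:
            for face in faces:
                t = render_label(label, face, scale).astype(np.float64)
                # border of background so even solid glyphs have variance
                t = np.pad(_trim(t), 2)
                self.templates.append((label, t))

    def recognise(self, patch: np.ndarray) -> tuple[str | None, float]:
        patch = _trim(np.asarray(patch, dtype=np.float64))
        if patch.size == 0:
            return None, 0.0
        patch = np.pad(patch, 2)
        best_label, best_score = None, 0.0
        for label, tmpl in self.templates:
            p = resize(patch, tmpl.shape, anti_aliasing=True)
            if p.std() == 0 or tmpl.std() == 0:
                continue
            r = float(np.corrcoef(p.ravel(), tmpl.ravel())[0, 1])
            if r > best_score:
                best_label, best_score = label, r
        return best_label, max(0.0, best_score)


def _trim(arr: np.ndarray) -> np.ndarray:
    """Crop an array to its nonzero bounding box."""
    nz = np.nonzero(arr)
    if nz[0].size == 0:
        return arr[:0, :0]
    return arr[nz[0].min(): nz[0].max() + 1, nz[1].min(): nz[1].max() + 1]


def remove_baseline_for_ocr(
    bin_img: BinaryInkImage,
    layout: LayoutModel,
    params: PipelineParams = DEFAULT_PARAMS,
) -> BinaryInkImage:
    """Clear ink on and immediately around each baseline, in a working copy.

    Lead names printed against the isoelectric line merge with the trace
    into one oversized component that the object filter rejects; clearing
    a +/-1 px band around each detected baseline separates them.  The
    original image is untouched.
    """
    ink = bin_img.ink.copy()
    hw = params.baseline_clear_halfwidth_px
    for b in layout.baselines:
        ink[max(0, b.y_px - hw): b.y_px + hw + 1, :] = False
    return BinaryInkImage(ink, dpi=bin_img.dpi)


def recognise_lead_names(
    objects: list[InkObject],
    bin_img: BinaryInkImage,
    recogniser,
    layout: LayoutModel,
    params: PipelineParams = DEFAULT_PARAMS,
) -> list[NamedBox]:
    """Score candidates against the vocabulary; keep confident, unique hits.

    Each box is assigned to the row whose vertical band contains its centre
    (nearest baseline when bands are absent).  At most one box per
    (row, label) survives — the most confident.  A recogniser failure on an
    object skips that object; it is never fatal.
    """
    boxes: list[NamedBox] = []
    for obj in objects:
        x0, y0, x1, y1 = obj.bbox
        patch = bin_img.ink[y0:y1, x0:x1]
        try:
            label, conf = recogniser.recognise(patch)
        except Exception:  # noqa: BLE001 - pluggable recogniser, stay alive
            log.warning("recogniser failed on object %s; skipped", obj.bbox, exc_info=True)
            continue
        if label is None or conf < params.confidence_threshold:
            continue
        cy = (y0 + y1) / 2.0
        row = _assign_row(cy, layout)
        if row is None:
            continue
        boxes.append(NamedBox(label=label, bbox=obj.bbox, confidence=conf, row=row))
    # one box per (row, label): keep the most confident
    best: dict[tuple[int, str], NamedBox] = {}
    for b in boxes:
        key = (b.row, b.label)
        if key not in best or b.confidence > best[key].confidence:
            best[key] = b
    return sorted(best.values(), key=lambda b: (b.row, b.bbox[0]))


def _assign_row(cy: float, layout: LayoutModel) -> int | None:
    if layout.bands:
        for i, band in enumerate(layout.bands):
            if band.y_top_px <= cy <= band.y_bottom_px:
                return i
        return None
    ys = [b.y_px for b in layout.baselines]
    return int(np.argmin([abs(cy - y) for y in ys])) if ys else None


def infer_missing_names(
    found: list[NamedBox], layout: LayoutModel
) -> NameGrid:
    """Fill the expected name grid, extrapolating positions for missed names.

    Missing cells get their x position from the same column in other rows
    when available, otherwise from the median column spacing of the names
    found in the same row; box size and height-above-baseline come from the
    medians of the found boxes.  Filled boxes are flagged ``inferred``.

    Raises
    ------
    LeadNameDetectionError
        If not a single name was recognised anywhere on the page.
    """
    if not found:
        raise LeadNameDetectionError("lead name detection failed: no names recognised")
    expected = EXPECTED_GRIDS.get(layout.layout_kind)
    if expected is None:
        # Unknown layout: keep what was found, row by row, no inference.
        rows: list[list[NamedBox]] = [[] for _ in range(layout.n_rows)]
        for b in found:
            rows[b.row].append(b)
        for r in rows:
            r.sort(key=lambda b: b.bbox[0])
            for c, b in enumerate(r):
                b.col = c
        return NameGrid(rows=rows, layout_kind=layout.layout_kind)

    n_rows = len(expected)
    # Index found boxes by (row, label); boxes whose label does not belong
    # to their row in the expected grid are treated as misrecognitions.
    by_cell: dict[tuple[int, int], NamedBox] = {}
    for b in found:
        if b.row >= n_rows:
            continue
        row_labels = expected[b.row]
        if b.label in row_labels:
            c = row_labels.index(b.label)
            cur = by_cell.get((b.row, c))
            if cur is None or b.confidence > cur.confidence:
                b.col = c
                by_cell[(b.row, c)] = b
    # Rhythm strip (single-name row of a 3x4 page): read whatever label was
    # found there, falling back to lead II.
    if layout.layout_kind == "3x4_rhythm":
        r = n_rows - 1
        if (r, 0) not in by_cell:
            rhythm_found = [b for b in found if b.row == r]
            if rhythm_found:
                b = max(rhythm_found, key=lambda b: b.confidence)
                b.col = 0
                by_cell[(r, 0)] = b
            else:
                log.warning("rhythm-strip label not detected; assuming lead II")
    if not by_cell:
        raise LeadNameDetectionError(
            "lead name detection failed: no recognised name fits the layout"
        )

    widths = [b.bbox[2] - b.bbox[0] for b in by_cell.values()]
    heights = [b.bbox[3] - b.bbox[1] for b in by_cell.values()]
    med_w = int(np.median(widths))
    med_h = int(np.median(heights))
    # Height of the box bottom above its row's baseline.
    base_of = {i: bl.y_px for i, bl in enumerate(layout.baselines)}
    rises = [base_of[b.row] - b.bbox[3] for b in by_cell.values() if b.row in base_of]
    med_rise = int(np.median(rises)) if rises else 0

    # Median column spacing from found pairs in the same row.
    pitches = []
    for r in range(n_rows):
        row_found = sorted(
            (b for (rr, _), b in by_cell.items() if rr == r), key=lambda b: b.col
        )
        for a, b in zip(row_found, row_found[1:]):
            if b.col != a.col:
                pitches.append((b.bbox[0] - a.bbox[0]) / (b.col - a.col))
    med_pitch = float(np.median(pitches)) if pitches else None

    rows_out: list[list[NamedBox]] = []
    for r, row_labels in enumerate(expected):
        row_boxes: list[NamedBox] = []
        for c, label in enumerate(row_labels):
            b = by_cell.get((r, c))
            if b is None:
                x0 = _infer_x0(r, c, by_cell, n_rows, med_pitch)
                if x0 is None:
                    raise LeadNameDetectionError(
                        f"cannot place name {label!r} (row {r}): too few anchors"
                    )
                y1 = base_of.get(r, 0) - med_rise
                b = NamedBox(
                    label=label,
                    bbox=(int(round(x0)), y1 - med_h, int(round(x0)) + med_w, y1),
                    confidence=0.0,
                    row=r,
                    col=c,
                    inferred=True,
                )
            row_boxes.append(b)
        rows_out.append(row_boxes)
    return NameGrid(rows=rows_out, layout_kind=layout.layout_kind)


def _infer_x0(
    r: int,
    c: int,
    by_cell: dict[tuple[int, int], NamedBox],
    n_rows: int,
    med_pitch: float | None,
) -> float | None:
    """x0 for a missing cell: same column in other rows, else row spacing."""
    same_col = [b.bbox[0] for (rr, cc), b in by_cell.items() if cc == c and rr != r]
    if same_col:
        return float(np.median(same_col))
    anchors = [(cc, b.bbox[0]) for (rr, cc), b in by_cell.items() if rr == r]
    if anchors and med_pitch is not None:
        cc0, x0 = min(anchors, key=lambda a: abs(a[0] - c))
        return x0 + (c - cc0) * med_pitch
    # Fall back to any row's anchor plus pitch extrapolation.
    anchors = [(cc, b.bbox[0]) for (_, cc), b in by_cell.items()]
    if anchors and med_pitch is not None:
        cc0, x0 = min(anchors, key=lambda a: abs(a[0] - c))
        return x0 + (c - cc0) * med_pitch
    return None


@dataclass
class LeadCrop:
    """One lead's binary sub-image with its local baseline and page offsets."""

    label: str
    ink: np.ndarray
    baseline_y_local: int
    x_offset_global: int
    y_offset_global: int
    row: int = -1
    col: int = -1
    inferred_name: bool = False

    @property
    def width_px(self) -> int:
        return self.ink.shape[1]

    @property
    def height_px(self) -> int:
        return self.ink.shape[0]


def crop_leads(
    bin_img: BinaryInkImage,
    layout: LayoutModel,
    names: NameGrid,
    params: PipelineParams = DEFAULT_PARAMS,
) -> list[LeadCrop]:
    """Cut one binary sub-image per lead from the name grid and row bands.

    A lead spans from the end of its own name box to the start of the next
    name in the row.  Rightmost (and single) leads have no next name: they
    extend by the maximum signal span observed in the other leads, or to
    the right image margin when the page has no inner leads at all.
    """
    if not layout.bands:
        raise ValueError("layout has no vertical bands; run vertical_anchors first")
    W = bin_img.width_px
    spans: list[tuple[int, int, int, NamedBox]] = []  # x_start, x_end(-1=open), row, box
    inner_widths: list[int] = []
    single_rows: set[int] = set()
    for r, row_boxes in enumerate(names.rows):
        ordered = sorted(row_boxes, key=lambda b: b.bbox[0])
        if len(ordered) == 1:
            single_rows.add(r)
        for i, b in enumerate(ordered):
            x_start = b.bbox[2]
            if i + 1 < len(ordered):
                x_end = ordered[i + 1].bbox[0]
                if x_end <= x_start:
                    raise AnchorGeometryError(
                        f"anchor geometry error: lead {b.label!r} span "
                        f"[{x_start}, {x_end}) is inverted"
                    )
                inner_widths.append(x_end - x_start)
            else:
                x_end = -1
            spans.append((x_start, x_end, r, b))
    max_inner = max(inner_widths) if inner_widths else None

    crops: list[LeadCrop] = []
    for x_start, x_end, r, b in spans:
        if x_end < 0:
            if r in single_rows or max_inner is None:
                # whole-row strips (rhythm, 12x1/3x1 rows) run to the margin
                x_end = W
            else:
                x_end = min(W, x_start + max_inner)
        band = layout.bands[r]
        y0, y1 = band.y_top_px, band.y_bottom_px + 1
        if x_end <= x_start:
            raise AnchorGeometryError(
                f"anchor geometry error: empty span for lead {b.label!r}"
            )
        crops.append(
            LeadCrop(
                label=b.label,
                ink=bin_img.ink[y0:y1, x_start:x_end].copy(),
                baseline_y_local=band.baseline_y_px - y0,
                x_offset_global=x_start,
                y_offset_global=y0,
                row=r,
                col=b.col,
                inferred_name=b.inferred,
            )
        )
    return crops
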