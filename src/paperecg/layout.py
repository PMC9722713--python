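"""Baseline detection and layout inference.

The isoelectric line of each printed lead row is a near-horizontal run of
ink spanning most of the page.  A Hough transform restricted to a narrow
angular window around the horizontal finds these rows; collinear segments
separated by small gaps (inter-lead spaces, lead-name gaps) are merged, and
lines covering less than a fixed fraction of the page width are discarded.
The surviving baselines give the row count, from which the printed lead
configuration (3x4 with rhythm strip, 6x2, 12x1, 3x1) is inferred, and each
row receives a vertical anchor band bounding its trace excursions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NoBaselinesError
from .image_io import BinaryInkImage
from .params import DEFAULT_PARAMS, PipelineParams

#: Recognised printed configurations.
LAYOUT_3X4_RHYTHM = "3x4_rhythm"
LAYOUT_3X4 = "3x4"
LAYOUT_6X2 = "6x2"
LAYOUT_12X1 = "12x1"
LAYOUT_3X1 = "3x1"
LAYOUT_UNKNOWN = "unknown"


@dataclass(frozen=True)
class Baseline:
    """A detected isoelectric line.

    ``y_px`` is the row index at the image's horizontal centre; the line may
    be tilted by up to the Hough angular window.  ``support`` is the Hough
    accumulator strength (ink pixel count on the line).
    """

    y_px: int
    x_start_px: int
    x_end_px: int
    support: int
    angle_deg: float = 0.0

    @property
    def span_px(self) -> int:
        return self.x_end_px - self.x_start_px


@dataclass(frozen=True)
class VerticalBand:
    """Vertical crop band of one lead row, baseline centred."""

    baseline_y_px: int
    y_top_px: int
    y_bottom_px: int

    @property
    def height_px(self) -> int:
        return self.y_bottom_px - self.y_top_px


@dataclass
class LayoutModel:
    """Detected page structure: baselines top-to-bottom, bands, layout kind."""

    baselines: list[Baseline]
    layout_kind: str = LAYOUT_UNKNOWN
    bands: list[VerticalBand] = field(default_factory=list)
    names_per_row: list[int] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.baselines)

    def to_dict(self) -> dict:
        return {
            "layout_kind": self.layout_kind,
            "n_rows": self.n_rows,
            "baselines": [
                {
                    "y_px": b.y_px,
                    "x_start_px": b.x_start_px,
                    "x_end_px": b.x_end_px,
                    "support": b.support,
                    "angle_deg": b.angle_deg,
                }
                for b in self.baselines
            ],
            "bands": [
                {"baseline_y_px": bd.baseline_y_px, "y_top_px": bd.y_top_px, "y_bottom_px": bd.y_bottom_px}
                for bd in self.bands
            ],
            "names_per_row": self.names_per_row,
        }


def _merged_span(xs: np.ndarray, max_gap: float) -> tuple[int, int, int]:
    """Longest chain of x-coverage after merging gaps <= max_gap.

    Returns (x_start, x_end_exclusive, covered_pixel_count) of the best
    merged run of occupied columns.
    """
    xs = np.unique(xs)
    if xs.size == 0:
        return 0, 0, 0
    gaps = np.diff(xs)
    breaks = np.nonzero(gaps > max_gap)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [xs.size - 1]))
    spans = xs[ends] - xs[starts]
    best = int(np.argmax(spans))
    lo, hi = int(xs[starts[best]]), int(xs[ends[best]])
    count = int(ends[best] - starts[best] + 1)
    return lo, hi + 1, count


def detect_baselines(
    bin_img: BinaryInkImage, params: PipelineParams = DEFAULT_PARAMS
) -> list[Baseline]:
    """Find near-horizontal baselines with a constrained Hough transform.

    The accumulator covers angles in ``+/- hough_angle_limit_deg`` (step
    ``hough_angle_step_deg``) and integer intercepts.  For each peak the
    supporting ink pixels' column coverage is computed; collinear segments
    separated by gaps of at most ``merge_gap_frac`` of the width are merged
    and lines whose merged span is below ``min_line_width_frac`` of the
    width are discarded.  Near-duplicate lines are collapsed to the
    strongest with non-maximum suppression over a window of
    ``nms_spacing_frac`` times the median row spacing.

    Raises
    ------
    ValueError
        If the ink image is blank (precondition).
    NoBaselinesError
        If no line survives the constraints.
    """
    if bin_img.ink_count == 0:
        raise ValueError("blank ink image: baseline detection needs >= 1 ink pixel")
    H, W = bin_img.ink.shape
    ys, xs = np.nonzero(bin_img.ink)
    ys = ys.astype(np.float64)
    xs_f = xs.astype(np.float64)

    n_steps = int(round(params.hough_angle_limit_deg / params.hough_angle_step_deg))
    angles = np.arange(-n_steps, n_steps + 1) * params.hough_angle_step_deg
    max_gap = params.merge_gap_frac * W
    min_span = params.min_line_width_frac * W
    x_mid = W / 2.0

    candidates: list[Baseline] = []
    for ang in angles:
        slope = np.tan(np.deg2rad(ang))
        # Intercept measured at the image centre so tilted lines of one row
        # fall in the same cell regardless of where their pixels sit.
        b = np.rint(ys - slope * (xs_f - x_mid)).astype(np.int64)
        valid = (b >= 0) & (b < H)
        counts = np.bincount(b[valid], minlength=H)
        # A plausible row must at least have min_span pixels' worth of ink
        # spread over the page; cheap pre-filter before span analysis.
        for b0 in np.nonzero(counts >= 0.5 * min_span)[0]:
            on_line = valid & (b == b0)
            lo, hi, covered = _merged_span(xs[on_line], max_gap)
            if hi - lo >= min_span:
                candidates.append(
                    Baseline(
                        y_px=int(b0),
                        x_start_px=lo,
                        x_end_px=hi,
                        support=int(counts[b0]),
                        angle_deg=float(ang),
                    )
                )
    if not candidates:
        raise NoBaselinesError("no baselines detected")

    kept = _nms(candidates, min_sep=5.0)
    if len(kept) > 1:
        spacing = float(np.median(np.diff(sorted(b.y_px for b in kept))))
        if spacing > 0:
            kept = _nms(candidates, min_sep=params.nms_spacing_frac * spacing)
    return sorted(kept, key=lambda b: b.y_px)


def _nms(candidates: list[Baseline], min_sep: float) -> list[Baseline]:
    """Greedy strongest-first suppression of lines closer than min_sep in y."""
    kept: list[Baseline] = []
    for cand in sorted(candidates, key=lambda b: (-b.support, b.y_px)):
        if all(abs(cand.y_px - k.y_px) >= min_sep for k in kept):
            kept.append(cand)
    return kept


def infer_layout(
    baselines: list[Baseline], names_per_row: list[int] | None = None
) -> LayoutModel:
    """Assign a layout kind from the row count and lead names per row.

    12 rows -> 12x1; 4 rows with 4-name lead rows -> 3x4 + rhythm strip;
    3 rows with 4 names -> plain 3x4; 3 rows with 1 name -> 3x1; 6 rows
    with 2 names -> 6x2.  Anything else is ``unknown``, which is still
    digitisable row by row.
    """
    if not baselines:
        raise ValueError("infer_layout requires >= 1 baseline")
    n = len(baselines)
    max_names = max(names_per_row) if names_per_row else 0
    kind = LAYOUT_UNKNOWN
    if n == 12:
        kind = LAYOUT_12X1
    elif n == 4 and max_names >= 2:
        # multi-name rows + a 4th row: 3x4 grid with a rhythm strip, even
        # when some names were missed (they are repaired from spacing)
        kind = LAYOUT_3X4_RHYTHM
    elif n == 3 and max_names >= 2:
        kind = LAYOUT_3X4
    elif n == 6 and max_names >= 2:
        kind = LAYOUT_6X2
    elif n == 3 and max_names == 1:
        kind = LAYOUT_3X1
    return LayoutModel(
        baselines=sorted(baselines, key=lambda b: b.y_px),
        layout_kind=kind,
        names_per_row=list(names_per_row or []),
    )


def vertical_anchors(
    layout: LayoutModel,
    image_height: int,
    params: PipelineParams = DEFAULT_PARAMS,
) -> LayoutModel:
    """Attach a vertical band to each row: baseline +/- 0.7 x neighbour gap.

    ``d`` is the distance to the nearer neighbouring baseline (edge rows
    reuse their single neighbour's distance; a single-row page uses half the
    image height).  Bands are clamped to the image borders.
    """
    ys = [b.y_px for b in layout.baselines]
    n = len(ys)
    bands: list[VerticalBand] = []
    for i, y in enumerate(ys):
        dists = []
        if i > 0:
            dists.append(y - ys[i - 1])
        if i < n - 1:
            dists.append(ys[i + 1] - y)
        d = min(dists) if dists else image_height / 2.0
        half = params.anchor_band_factor * d
        bands.append(
            VerticalBand(
                baseline_y_px=y,
                y_top_px=max(0, int(round(y - half))),
                y_bottom_px=min(image_height - 1, int(round(y + half))),
            )
        )
    layout.bands = bands
    return layout
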