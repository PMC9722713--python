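"""Pipeline constants.

All numeric constants of the digitisation method live in one dataclass so
that every stage reads the same configuration and everything is overridable
from a YAML file or CLI flags.  Units are stated per field.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml


@dataclass(frozen=True)
class PipelineParams:
    """Tunable constants of the digitisation pipeline.

    The defaults implement the published operating point of the method:
    a 0.94 grey threshold for grid suppression, a +/-2.5 degree Hough window
    for baselines, 80%-width line acceptance with 15%-width gap merging,
    0.7x/1.4x vertical anchor bands, the lead-name object filters, and the
    fixed 0.0025 mV/ms voltage-time ratio of 25 mm/s / 10 mm/mV paper.
    """

    # --- preprocess ---
    gray_threshold: float = 0.94          # grey value above which a pixel is background
    redaction_tol: float = 1.0 / 255.0    # row mean below this counts as "black"

    # --- layout (baseline Hough) ---
    hough_angle_limit_deg: float = 2.5    # |angle| window around horizontal
    hough_angle_step_deg: float = 0.5     # angular discretisation
    min_line_width_frac: float = 0.80     # lines shorter than this fraction of width are discarded
    merge_gap_frac: float = 0.15          # collinear gaps up to this fraction of width are merged
    nms_spacing_frac: float = 0.3         # NMS window as a fraction of median row spacing
    anchor_band_factor: float = 0.7       # band half-height = 0.7 x neighbour distance
    crop_height_factor: float = 1.4       # total crop height = 1.4 x neighbour distance

    # --- leadfind (name objects) ---
    wh_ratio_max: float = 5.0             # max(bbox side)/min(bbox side) above this -> rejected
    obj_min_px: int = 5                   # bbox side below this (pixels) -> rejected
    obj_max_px: int = 500                 # bbox side above this (pixels) -> rejected
    close_selem_px: int = 3               # square structuring element for dilation-then-erosion
    glyph_merge_gap_px: int = 6           # letters closer than this (and vertically overlapping) form one word
    confidence_threshold: float = 0.6     # template-match acceptance threshold
    baseline_clear_halfwidth_px: int = 1  # rows cleared around each baseline for OCR

    # --- extract ---
    trace_dilate_len_px: int = 5          # horizontal 1xN element bridging trace gaps
    record_duration_s: float = 10.0       # duration of the rhythm / longest strip
    vt_ratio_mv_per_ms: float = 0.0025    # 0.1 mV / 40 ms, fixed by 25 mm/s & 10 mm/mV paper
    paper_speed_mm_s: float = 25.0
    gain_mm_mv: float = 10.0

    def __post_init__(self) -> None:
        if self.merge_gap_frac >= self.min_line_width_frac:
            raise ValueError("merge_gap_frac must be < min_line_width_frac")
        if self.obj_min_px >= self.obj_max_px:
            raise ValueError("obj_min_px must be < obj_max_px")
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, (int, float)) and v <= 0:
                raise ValueError(f"{f.name} must be positive, got {v}")

    def replace(self, **kwargs) -> "PipelineParams":
        return dataclasses.replace(self, **kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineParams":
        """Load overrides from a YAML mapping; unknown keys are rejected."""
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown parameter(s) in {path}: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


DEFAULT_PARAMS = PipelineParams()
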