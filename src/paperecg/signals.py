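"""Digital signal containers shared by the extraction and synthesis code."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import IncompleteRecordError

#: Standard reporting order of the 12 leads; also the CSV column order.
LEAD_ORDER = ("I", "II", "III", "avr", "avl", "avf", "v1", "v2", "v3", "v4", "v5", "v6")

#: Lead sets implied by each printed configuration (3x1 pages carry 3 leads).
LAYOUT_LEADS = {
    "3x4_rhythm": LEAD_ORDER,
    "3x4": LEAD_ORDER,
    "6x2": LEAD_ORDER,
    "12x1": LEAD_ORDER,
    "3x1": ("I", "II", "v1"),
}

#: Number of time columns the page splits the record into, per layout.
LAYOUT_N_COLS = {"3x4_rhythm": 4, "3x4": 4, "6x2": 2, "12x1": 1, "3x1": 1, "unknown": 1}


@dataclass
class DigitalSignal:
    """One lead's calibrated voltage-time series.

    ``t_ms`` is uniformly spaced with step ``time_res_ms_per_px``;
    ``volt_res_mv_per_px`` always equals ``time_res * 0.0025`` (the fixed
    voltage-time ratio of 25 mm/s, 10 mm/mV paper).
    """

    lead: str
    t_ms: np.ndarray
    v_mv: np.ndarray
    time_res_ms_per_px: float
    volt_res_mv_per_px: float
    col: int = 0  # page column the lead was printed in (0-based)

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.float64)
        self.v_mv = np.asarray(self.v_mv, dtype=np.float64)
        if self.t_ms.shape != self.v_mv.shape:
            raise ValueError("t_ms and v_mv must have identical shape")
        if self.t_ms.size >= 2 and not np.all(np.diff(self.t_ms) > 0):
            raise ValueError("time axis must be strictly increasing")
        if not np.all(np.isfinite(self.v_mv)):
            raise ValueError("voltages must be finite")

    @property
    def n_samples(self) -> int:
        return self.t_ms.size

    @property
    def duration_ms(self) -> float:
        """Reconstructed duration: sample count times the time resolution."""
        return self.n_samples * self.time_res_ms_per_px

    def shifted(self, offset_ms: float) -> "DigitalSignal":
        return DigitalSignal(
            lead=self.lead,
            t_ms=self.t_ms + offset_ms,
            v_mv=self.v_mv,
            time_res_ms_per_px=self.time_res_ms_per_px,
            volt_res_mv_per_px=self.volt_res_mv_per_px,
            col=self.col,
        )


@dataclass
class ECGRecord:
    """A digitised record: the page's leads plus an optional rhythm strip."""

    signals: dict[str, DigitalSignal]
    layout_kind: str = "unknown"
    rhythm: DigitalSignal | None = None
    calibration: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = LAYOUT_LEADS.get(self.layout_kind)
        if expected is not None and set(self.signals) != set(expected):
            missing = set(expected) - set(self.signals)
            extra = set(self.signals) - set(expected)
            raise IncompleteRecordError(
                f"incomplete record for layout {self.layout_kind}: "
                f"missing {sorted(missing)}, unexpected {sorted(extra)}"
            )

    @property
    def lead_order(self) -> tuple[str, ...]:
        return tuple(l for l in LEAD_ORDER if l in self.signals)

    def __getitem__(self, lead: str) -> DigitalSignal:
        return self.signals[lead]
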