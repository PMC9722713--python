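"""The 13-column spreadsheet format.

Column 1 is the time axis (ms); columns 2-13 are the 12 leads' voltages
(mV) in standard order.  On multi-column pages each lead only has samples
inside its own 2.5 s (or 5 s) window, so cells outside a lead's span are
empty.  Dialect: comma separator, '.' decimal, UTF-8, LF endings, 6
significant digits — fixed so fixture files are bit-reproducible.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .signals import LEAD_ORDER, DigitalSignal, ECGRecord

CSV_COLUMNS = ("time_ms",) + LEAD_ORDER


def write_csv(record: ECGRecord, path: str | Path, resample_hz: float | None = None) -> None:
    """Write a record as the 13-column CSV.

    ``resample_hz`` optionally resamples every lead onto a uniform grid
    (e.g. 500 Hz) instead of the per-pixel time lattice, which varies with
    scan width.
    """
    sigs = {lead: record.signals[lead] for lead in record.lead_order}
    if resample_hz:
        step = 1000.0 / resample_hz
        t_max = max(s.t_ms[-1] for s in sigs.values())
        times = np.arange(0.0, t_max + step / 2, step)
    else:
        times = np.unique(np.concatenate([s.t_ms for s in sigs.values()]))
    frame = pd.DataFrame({"time_ms": times})
    for lead in LEAD_ORDER:
        col = np.full(times.size, np.nan)
        s = sigs.get(lead)
        if s is not None:
            inside = (times >= s.t_ms[0]) & (times <= s.t_ms[-1])
            if resample_hz:
                col[inside] = np.interp(times[inside], s.t_ms, s.v_mv)
            else:
                # exact placement: only instants the lead actually sampled
                idx = np.searchsorted(times, s.t_ms)
                col[idx] = s.v_mv
        frame[lead] = col
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(
        path, index=False, na_rep="", float_format="%.6g", lineterminator="\n"
    )


def read_csv(path: str | Path) -> dict[str, DigitalSignal]:
    """Read a 13-column CSV back into per-lead signals (empty cells dropped)."""
    frame = pd.read_csv(path)
    missing = set(CSV_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"not a 13-column record: missing columns {sorted(missing)}")
    out: dict[str, DigitalSignal] = {}
    t_all = frame["time_ms"].to_numpy(dtype=float)
    for lead in LEAD_ORDER:
        v = frame[lead].to_numpy(dtype=float)
        mask = ~np.isnan(v)
        if mask.sum() < 2:
            continue
        t = t_all[mask]
        steps = np.diff(t)
        out[lead] = DigitalSignal(
            lead=lead,
            t_ms=t,
            v_mv=v[mask],
            time_res_ms_per_px=float(np.median(steps)),
            volt_res_mv_per_px=float(np.median(steps)) * 0.0025,
        )
    return out
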