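"""Validation metrics: Pearson correlation and RMSE after alignment.

A digitised lead is compared to its reference by resampling it onto the
reference's time grid over their overlapping span.  Crop anchors are only
pixel-accurate, so a bounded integer-lag search (cross-correlation over
multiples of the reference sampling step, default +/-40 ms) absorbs the
constant latency this quantisation introduces before r and RMSE are
computed; ties favour zero lag, so identical signals always report
r = 1, RMSE = 0 at lag 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .signals import DigitalSignal


@dataclass(frozen=True)
class LeadComparison:
    """Agreement between a reference and a digitised lead."""

    lead: str
    pearson_r: float
    rmse_mv: float
    n_samples: int
    p_value: float
    lag_ms: float = 0.0


def align_and_compare(
    truth: DigitalSignal,
    digitised: DigitalSignal,
    max_lag_ms: float = 40.0,
) -> LeadComparison:
    """Pearson r, RMSE (mV) and two-sided p over the overlapping time span.

    Raises
    ------
    ValueError
        If the signals share fewer than two reference samples of overlap.
    """
    if truth.n_samples == 0 or digitised.n_samples == 0:
        raise ValueError("both signals must be non-empty")
    t0 = max(truth.t_ms[0], digitised.t_ms[0])
    t1 = min(truth.t_ms[-1], digitised.t_ms[-1])
    sel = (truth.t_ms >= t0) & (truth.t_ms <= t1)
    tt = truth.t_ms[sel]
    tv = truth.v_mv[sel]
    if tt.size < 2:
        raise ValueError("overlap shorter than 2 samples")

    dt = truth.time_res_ms_per_px
    n_lags = int(max_lag_ms // dt) if max_lag_ms > 0 else 0
    lags = np.arange(-n_lags, n_lags + 1) * dt
    lags = lags[np.argsort(np.abs(lags), kind="stable")]  # prefer small |lag|

    # lag > 0 means the digitised signal lags the reference; the search
    # maximises |r| so an inverted signal still reports r = -1 at lag 0
    best_lag, best_r, best_d = 0.0, -np.inf, None
    for lag in lags:
        d = np.interp(tt, digitised.t_ms - lag, digitised.v_mv)
        if np.std(d) == 0 or np.std(tv) == 0:
            r = 0.0
        else:
            r = float(np.corrcoef(tv, d)[0, 1])
        if abs(r) > best_r:
            best_lag, best_r, best_d = float(lag), abs(r), d
    assert best_d is not None
    rmse = float(np.sqrt(np.mean((tv - best_d) ** 2)))
    if np.std(best_d) == 0 or np.std(tv) == 0:
        r_final, p = 0.0, 1.0
    else:
        r_final, p = stats.pearsonr(tv, best_d)
    return LeadComparison(
        lead=truth.lead,
        pearson_r=float(r_final),
        rmse_mv=rmse,
        n_samples=int(tt.size),
        p_value=float(p),
        lag_ms=best_lag,
    )


def compare_record(
    truth: dict[str, DigitalSignal],
    record,
    max_lag_ms: float = 40.0,
) -> dict[str, LeadComparison]:
    """Per-lead comparison of a digitised record against reference signals."""
    out: dict[str, LeadComparison] = {}
    for lead in record.lead_order:
        if lead in truth:
            out[lead] = align_and_compare(truth[lead], record[lead], max_lag_ms)
    return out
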