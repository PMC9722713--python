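"""Seeded 12-lead test waveforms.

Each beat is a sum of five Gaussians (P, Q, R, S, T) tiled at the heart
rate; every lead is the same beat train scaled by a per-lead factor (aVR
negative).  This is a deliberately simple, closed-form, fully seeded model:
amplitudes are controllable for overlap studies and the analytic maximum of
the Gaussian sum serves as an oracle.  No physiological realism beyond
plausible amplitudes and intervals is claimed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..signals import LEAD_ORDER, DigitalSignal

#: (amplitude mV, centre ms within the beat, Gaussian sigma ms)
DEFAULT_WAVES: dict[str, tuple[float, float, float]] = {
    "P": (0.15, 200.0, 25.0),
    "Q": (-0.10, 340.0, 10.0),
    "R": (1.00, 360.0, 15.0),
    "S": (-0.20, 385.0, 10.0),
    "T": (0.30, 600.0, 60.0),
}

#: Per-lead amplitude scale factors (aVR inverted, as on real tracings).
DEFAULT_LEAD_SCALES: dict[str, float] = {
    "I": 0.60, "II": 1.00, "III": 0.45,
    "avr": -0.50, "avl": 0.40, "avf": 0.70,
    "v1": 0.50, "v2": 0.70, "v3": 0.90,
    "v4": 1.00, "v5": 0.85, "v6": 0.70,
}


@dataclass(frozen=True)
class WaveParams:
    """Parameters of the synthetic beat train.

    ``hr_jitter`` and ``amp_jitter`` are the half-widths of seeded uniform
    multiplicative perturbations applied per record (heart rate) and per
    wave component (amplitudes); set them to 0 for closed-form tests.
    """

    heart_rate_bpm: float = 60.0
    waves: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_WAVES)
    )
    lead_scales: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LEAD_SCALES)
    )
    sampling_rate_hz: float = 500.0
    duration_s: float = 10.0
    seed: int = 0
    hr_jitter: float = 0.08
    amp_jitter: float = 0.10

    def __post_init__(self) -> None:
        if self.heart_rate_bpm <= 0 or self.sampling_rate_hz <= 0 or self.duration_s <= 0:
            raise ValueError("rate and duration parameters must be positive")
        for name, (_, _, sigma) in self.waves.items():
            if sigma <= 0:
                raise ValueError(f"wave {name}: sigma must be positive")


def generate_waveforms(params: WaveParams = WaveParams()) -> dict[str, DigitalSignal]:
    """Generate the 12 ground-truth lead signals, keyed by lead label.

    Deterministic for a fixed :class:`WaveParams` (including seed).
    """
    rng = np.random.default_rng(params.seed)
    hr = params.heart_rate_bpm * (1.0 + params.hr_jitter * rng.uniform(-1, 1))
    amp_mult = {
        name: 1.0 + params.amp_jitter * rng.uniform(-1, 1) for name in params.waves
    }
    rr_ms = 60000.0 / hr
    dt_ms = 1000.0 / params.sampling_rate_hz
    n = int(round(params.duration_s * params.sampling_rate_hz))
    t = np.arange(n) * dt_ms

    beat = np.zeros(n)
    n_beats = int(np.ceil(params.duration_s * 1000.0 / rr_ms)) + 1
    for k in range(n_beats):
        t0 = k * rr_ms
        for name, (amp, centre, sigma) in params.waves.items():
            beat += (amp * amp_mult[name]) * np.exp(
                -((t - t0 - centre) ** 2) / (2.0 * sigma**2)
            )

    time_res = dt_ms
    volt_res = time_res * 0.0025
    return {
        lead: DigitalSignal(
            lead=lead,
            t_ms=t,
            v_mv=params.lead_scales[lead] * beat,
            time_res_ms_per_px=time_res,
            volt_res_mv_per_px=volt_res,
        )
        for lead in LEAD_ORDER
    }
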