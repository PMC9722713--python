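"""Trace isolation, median collapse, calibration, record assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from paperecg import (
    CalibrationError,
    EmptyLeadError,
    IncompleteRecordError,
    LeadCrop,
    PixelSeries,
    assemble_record,
    calibrate,
    collapse_to_series,
    isolate_trace,
)
from paperecg.layout import Baseline, LayoutModel
from paperecg.signals import LEAD_ORDER, DigitalSignal


def _crop(ink, baseline=None, label="II"):
    return LeadCrop(
        label=label,
        ink=ink,
        baseline_y_local=baseline if baseline is not None else ink.shape[0] // 2,
        x_offset_global=0,
        y_offset_global=0,
    )


class TestIsolateTrace:
    def test_keeps_trace_drops_speck_and_neighbour_tip(self):
        ink = np.zeros((80, 300), dtype=bool)
        xs = np.arange(300)
        ys = (40 + 10 * np.sin(xs / 20)).astype(int)
        ink[ys, xs] = True                       # the trace
        ink[5:8, 100:104] = True                 # 12 px noise speck
        ink[70:80, 200:203] = True               # neighbouring lead's QRS tip
        out = isolate_trace(_crop(ink))
        assert out.ink[ys, xs].all()
        assert not out.ink[5:8, 100:104].any()
        assert not out.ink[70:80, 200:203].any()

    def test_single_object_unchanged(self):
        ink = np.zeros((40, 100), dtype=bool)
        ink[20, 10:90] = True
        out = isolate_trace(_crop(ink))
        np.testing.assert_array_equal(out.ink, ink)

    def test_dilation_bridges_small_horizontal_gaps(self):
        ink = np.zeros((40, 100), dtype=bool)
        ink[20, 10:48] = True
        ink[20, 51:90] = True  # 3 px gap, below the 1x5 bridge length
        ink[35:39, 30:34] = True  # larger off-trace blob would win if split
        out = isolate_trace(_crop(ink))
        assert out.ink[20, 10:48].all() and out.ink[20, 51:90].all()
        assert not out.ink[35:39].any()

    def test_empty_crop_raises_with_label(self):
        with pytest.raises(EmptyLeadError) as err:
            isolate_trace(_crop(np.zeros((10, 10), dtype=bool), label="v5"))
        assert err.value.label == "v5"

    def test_synthetic_crop_retains_own_lead_ink(self, truth_3x4, digitised_3x4):
        _, debug = digitised_3x4
        shift = truth_3x4.redaction_rows
        crop = next(c for c in debug["crops"] if c.label == "v2" and c.row == 1)
        cleaned = isolate_trace(crop)
        rr, cc = truth_3x4.lead_ink_px[(1, 2)]
        rloc, cloc = rr - shift - crop.y_offset_global, cc - crop.x_offset_global
        ok = (
            (rloc >= 0) & (rloc < crop.height_px)
            & (cloc >= 0) & (cloc < crop.width_px)
        )
        assert cleaned.ink[rloc[ok], cloc[ok]].mean() >= 0.99


class TestCollapseToSeries:
    def test_odd_count_median(self):
        ink = np.zeros((20, 3), dtype=bool)
        ink[[10, 11, 12], 1] = True
        s = collapse_to_series(_crop(ink))
        assert list(s.x_px) == [1]
        assert list(s.y_px) == [11]

    def test_even_count_takes_lower_median(self):
        ink = np.zeros((20, 1), dtype=bool)
        ink[[10, 11, 12, 13], 0] = True
        s = collapse_to_series(_crop(ink))
        assert s.y_px[0] == 11

    def test_ink_free_columns_are_absent(self):
        ink = np.zeros((10, 5), dtype=bool)
        ink[3, [0, 2, 4]] = True
        s = collapse_to_series(_crop(ink))
        assert list(s.x_px) == [0, 2, 4]

    def test_empty_raises(self):
        with pytest.raises(EmptyLeadError):
            collapse_to_series(_crop(np.zeros((5, 5), dtype=bool)))

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_brute_force_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        ink = rng.random((25, 40)) < 0.15
        if not ink.any():
            return
        s = collapse_to_series(_crop(ink))
        for x, y in zip(s.x_px, s.y_px):
            rows = sorted(np.nonzero(ink[:, x])[0])
            assert y == rows[(len(rows) - 1) // 2]
        assert list(s.x_px) == sorted(np.nonzero(ink.any(axis=0))[0])


class TestCalibrate:
    def _series(self, xs, ys, baseline=100, lead="II"):
        return PixelSeries(
            x_px=np.asarray(xs), y_px=np.asarray(ys), baseline_y_px=baseline, lead=lead
        )

    def test_2500px_strip_gives_4ms_and_10uv_per_px(self):
        s = self._series([0, 1, 2], [100, 100, 100])
        sig = calibrate(s, rhythm_width_px=2500)
        assert sig.time_res_ms_per_px == 4.0
        assert sig.volt_res_mv_per_px == 0.01

    def test_sign_convention_40px_above_baseline_is_plus_0p4mv(self):
        s = self._series([0, 1], [100, 60])
        sig = calibrate(s, rhythm_width_px=2500)
        assert sig.v_mv[0] == 0.0
        assert sig.v_mv[1] == pytest.approx(0.40)

    @pytest.mark.parametrize("width", [640, 1231, 2461, 2500, 4922])
    def test_volt_time_ratio_exact(self, width):
        s = self._series([0, 5], [100, 90])
        sig = calibrate(s, rhythm_width_px=width)
        assert sig.volt_res_mv_per_px / sig.time_res_ms_per_px == 0.0025

    def test_gaps_interpolated_no_nan_monotone_time(self):
        s = self._series([0, 4, 10], [100, 80, 100])
        sig = calibrate(s, rhythm_width_px=1000)
        assert sig.n_samples == 11
        assert np.all(np.isfinite(sig.v_mv))
        assert np.all(np.diff(sig.t_ms) > 0)
        # midpoint of the 0->4 gap sits on the line between the endpoints
        assert sig.v_mv[2] == pytest.approx((sig.v_mv[0] + sig.v_mv[4]) / 2)

    def test_nonpositive_width_raises(self):
        with pytest.raises(CalibrationError):
            calibrate(self._series([0, 1], [5, 5]), rhythm_width_px=0)

    def test_duration_conservation_by_construction(self):
        s = self._series(np.arange(2461), np.full(2461, 50))
        sig = calibrate(s, rhythm_width_px=2461)
        assert sig.duration_ms == pytest.approx(10000.0, abs=1e-9)

    def test_r_peak_amplitude_recovered(self, truth_3x4, digitised_3x4):
        record, _ = digitised_3x4
        dig = record["II"]
        sel = (truth_3x4.waveforms["II"].t_ms >= dig.t_ms[0]) & (
            truth_3x4.waveforms["II"].t_ms <= dig.t_ms[-1]
        )
        true_peak = truth_3x4.waveforms["II"].v_mv[sel].max()
        assert abs(dig.v_mv.max() - true_peak) <= 2 * dig.volt_res_mv_per_px


class TestAssembleRecord:
    def _signals(self, cols=None):
        cols = cols or {}
        out = []
        for lead in LEAD_ORDER:
            out.append(
                DigitalSignal(
                    lead=lead,
                    t_ms=np.arange(5) * 4.0,
                    v_mv=np.zeros(5),
                    time_res_ms_per_px=4.0,
                    volt_res_mv_per_px=0.01,
                    col=cols.get(lead, 0),
                )
            )
        return out

    def _layout(self, kind, n_rows):
        bls = [Baseline(100 * i + 50, 0, 2500, 2500) for i in range(n_rows)]
        lay = LayoutModel(bls)
        lay.layout_kind = kind
        return lay

    def test_3x4_column_offsets_are_multiples_of_2p5s(self):
        cols = {"I": 0, "II": 0, "III": 0, "avr": 1, "avl": 1, "avf": 1,
                "v1": 2, "v2": 2, "v3": 2, "v4": 3, "v5": 3, "v6": 3}
        rec = assemble_record(self._signals(cols), self._layout("3x4_rhythm", 4))
        assert rec["I"].t_ms[0] == 0.0
        assert rec["avr"].t_ms[0] == 2500.0
        assert rec["v1"].t_ms[0] == 5000.0
        assert rec["v4"].t_ms[0] == 7500.0

    def test_12x1_all_start_at_zero(self):
        rec = assemble_record(self._signals(), self._layout("12x1", 12))
        assert all(rec[l].t_ms[0] == 0.0 for l in LEAD_ORDER)

    def test_duplicate_lead_raises(self):
        sigs = self._signals()
        sigs[0] = DigitalSignal(
            lead="v2", t_ms=np.arange(3) * 4.0, v_mv=np.zeros(3),
            time_res_ms_per_px=4.0, volt_res_mv_per_px=0.01,
        )
        with pytest.raises(IncompleteRecordError):
            assemble_record(sigs, self._layout("12x1", 12))

    def test_missing_lead_raises(self):
        with pytest.raises(IncompleteRecordError):
            assemble_record(self._signals()[:11], self._layout("12x1", 12))

    def test_3x1_record_carries_its_three_leads(self):
        sigs = [s for s in self._signals() if s.lead in ("I", "II", "v1")]
        rec = assemble_record(sigs, self._layout("3x1", 3))
        assert rec.lead_order == ("I", "II", "v1")
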