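"""Hilbert phase, unwrapping, ECG-BP phase shift and pulse transit time."""

import numpy as np
import pandas as pd
import pytest

from cardioemd import (
    IMFSet,
    NoCardiacIMFError,
    Signal,
    cumulative_phase,
    detect_beats,
    hilbert_phase,
    phase_shift,
    pulse_transit_time,
    select_cardiac_imf,
)


class TestSelectCardiacIMF:
    def _set(self, rows, rate):
        rows = np.asarray(rows)
        return IMFSet(rows, np.zeros(rows.shape[1]), rate, "eemd")

    def test_exact_tone_selected(self):
        t = np.arange(0, 10, 1 / 250)
        iset = self._set(
            [np.sin(2 * np.pi * 6 * t), np.sin(2 * np.pi * 3 * t),
             np.sin(2 * np.pi * 0.4 * t)],
            250.0,
        )
        assert select_cardiac_imf(iset, 3.0) == 1

    def test_out_of_band_raises(self):
        t = np.arange(0, 30, 1 / 100)
        iset = self._set([np.sin(2 * np.pi * 0.2 * t)], 100.0)
        with pytest.raises(NoCardiacIMFError):
            select_cardiac_imf(iset, 3.0)

    def test_ecg_like_train(self):
        # impulse-like R-wave train at 3 Hz: the fundamental-band IMF of its
        # decomposition should be selected with a frequency near 3 Hz
        from cardioemd import EnsembleParams, average_frequency, eemd

        rng = np.random.default_rng(0)
        t = np.arange(0, 20, 1 / 250)
        ecg = sum(
            np.exp(-0.5 * ((t - tr) / 0.012) ** 2)
            for tr in np.arange(0.2, 19.8, 1 / 3.0)
        ) + rng.normal(0, 0.03, t.size)
        dec = eemd(Signal(ecg, 250.0), EnsembleParams(ensemble_size=20, seed=2))
        idx = select_cardiac_imf(dec, 3.0)
        f = average_frequency(dec.imfs[idx], 250.0, "zero-crossing")
        assert abs(f - 3.0) / 3.0 <= 0.15


class TestHilbertPhase:
    def test_cosine_phase_ramp(self):
        t = np.arange(0, 10, 1 / 200)
        phi = cumulative_phase(hilbert_phase(np.cos(2 * np.pi * 2 * t)))
        sl = slice(200, -200)
        slope = np.polyfit(t[sl], phi[sl], 1)[0]
        assert slope == pytest.approx(2 * np.pi * 2, rel=0.01)

    def test_quadrature_pair_offset(self):
        t = np.arange(0, 10, 1 / 200)
        pc = hilbert_phase(np.cos(2 * np.pi * 2 * t))
        ps = hilbert_phase(np.sin(2 * np.pi * 2 * t))
        diff = np.angle(np.exp(1j * (pc - ps)))
        assert np.median(diff[200:-200]) == pytest.approx(np.pi / 2, abs=0.02)

    def test_one_cycle_accumulates_two_pi(self):
        t = np.arange(0, 10, 1 / 200)
        phi = cumulative_phase(hilbert_phase(np.cos(2 * np.pi * 1 * t)))
        one_cycle = phi[600] - phi[400]  # exactly 1 s apart, interior
        assert one_cycle == pytest.approx(2 * np.pi, rel=0.01)

    def test_all_zero_has_no_phase(self):
        with pytest.raises(ValueError):
            hilbert_phase(np.zeros(100))


class TestCumulativePhase:
    def test_single_wrap_corrected(self):
        raw = np.linspace(0, 3 * np.pi / 2, 100)
        wrapped = np.angle(np.exp(1j * raw))
        un = cumulative_phase(wrapped)
        np.testing.assert_allclose(un, raw, atol=1e-9)

    def test_k_cycles_accumulate(self):
        k = 7
        raw = np.linspace(0, 2 * np.pi * k, 5000)
        un = cumulative_phase(np.angle(np.exp(1j * raw)))
        assert (un[-1] - un[0]) == pytest.approx(2 * np.pi * k, rel=1e-6)

    def test_round_trip_constant_offset(self):
        t = np.linspace(0, 20, 2000)
        x = 2 * np.pi * 1.3 * t + 0.5 * np.sin(t)
        un = cumulative_phase(np.angle(np.exp(1j * x)))
        diff = un - x
        np.testing.assert_allclose(diff, diff[0], atol=1e-9)
        assert diff[0] == pytest.approx(round(diff[0] / (2 * np.pi)) * 2 * np.pi)


class TestPhaseShift:
    def _delayed_pair(self, tau, f=3.0, rate=1000.0, duration=20.0):
        t = np.arange(0, duration, 1 / rate)
        e = np.cos(2 * np.pi * f * t)
        b = np.cos(2 * np.pi * f * (t - tau))
        return e, b, t

    @pytest.mark.parametrize("tau", [0.06, 0.10, 0.14])
    def test_delay_maps_to_phase(self, tau):
        e, b, t = self._delayed_pair(tau)
        res = phase_shift(e, b, 1000.0)
        interior = res.shift_smoothed[1000:-1000]
        assert np.mean(interior) == pytest.approx(2 * np.pi * 3.0 * tau, rel=0.05)

    def test_zero_delay_zero_shift(self):
        e, b, _ = self._delayed_pair(0.0)
        res = phase_shift(e, e, 1000.0)
        assert abs(np.mean(res.shift_smoothed[1000:-1000])) <= 0.05

    def test_antisymmetry(self):
        e, b, _ = self._delayed_pair(0.1)
        ab = phase_shift(e, b, 1000.0)
        ba = phase_shift(b, e, 1000.0)
        np.testing.assert_allclose(ab.shift, -ba.shift, atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            phase_shift(np.ones(10), np.ones(11), 10.0)


def delayed_beat_fixture(tau=0.12, rate=1000.0, duration=20.0, f0=3.0):
    """ECG-like cardiac IMF and BP with systolic peaks trailing R by tau."""
    t = np.arange(0, duration, 1 / rate)
    ecg_cardiac = np.cos(2 * np.pi * f0 * (t - 0.2))  # R peaks at 0.2 + k/f0
    bp = 70 + 15 * (1 + np.cos(2 * np.pi * f0 * (t - 0.2 - tau)))
    return Signal(ecg_cardiac, rate), Signal(bp, rate), t


class TestPulseTransitTime:
    def test_recovers_constructed_delay(self):
        ecg_c, bp, _ = delayed_beat_fixture(tau=0.12)
        beats = detect_beats(bp)
        table = pulse_transit_time(ecg_c, beats, 3.0)
        assert table["ptt"].median() == pytest.approx(0.120, abs=0.010)

    def test_swapped_channels_yield_no_valid_beats(self):
        # negative delay: BP peaks precede the "R peaks" by construction
        ecg_c, bp, t = delayed_beat_fixture(tau=-0.12)
        beats = detect_beats(bp)
        table = pulse_transit_time(ecg_c, beats, 3.0)
        # each systolic peak is 213 ms after the *previous* R peak here, so
        # either NaN or implausibly long delays compared to the true 120 ms
        valid = table["ptt"].dropna()
        assert valid.empty or (valid > 0.15).all()

    def test_ptt_consistent_with_phase_shift(self):
        tau, f0 = 0.10, 3.0
        ecg_c, bp, t = delayed_beat_fixture(tau=tau)
        beats = detect_beats(bp)
        table = pulse_transit_time(ecg_c, beats, f0)
        bp_cardiac = np.cos(2 * np.pi * f0 * (t - 0.2 - tau))
        res = phase_shift(ecg_c.samples, bp_cardiac, 1000.0)
        shift_ratio = np.mean(res.shift_smoothed[2000:-2000]) / (2 * np.pi)
        ptt_ratio = table["ptt"].median() * f0
        assert shift_ratio == pytest.approx(ptt_ratio, rel=0.15)
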