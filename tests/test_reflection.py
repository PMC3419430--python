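"""Beat detection, wave separation, both reflection indexes, smoothing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cardioemd import (
    IMFSet,
    NoBeatsError,
    SeparationError,
    Signal,
    beat_amplitudes,
    cyclic_period,
    detect_beats,
    moving_average,
    referred_ri,
    reflection_index,
    separate_waves,
)
from cardioemd.significance import MCVerification


def pulse_train(rate=250.0, duration=10.0, f0=3.0, amp=30.0, base=70.0):
    t = np.arange(0, duration, 1 / rate)
    return Signal(base + amp * 0.5 * (1 - np.cos(2 * np.pi * f0 * t)), rate), t


class TestDetectBeats:
    def test_count_at_3hz(self):
        bp, _ = pulse_train()
        beats = detect_beats(bp)
        assert abs(len(beats) - 30) <= 1

    def test_peaks_match_windowed_argmax(self):
        bp, t = pulse_train()
        beats = detect_beats(bp)
        x = bp.samples
        for peak in beats["peak"].astype(int):
            lo = max(0, peak - 40)
            hi = min(x.size, peak + 41)
            assert x[peak] == np.max(x[lo:hi])

    def test_constant_signal_has_no_beats(self):
        with pytest.raises(NoBeatsError):
            detect_beats(Signal(np.full(1000, 80.0), 250.0))

    def test_onset_is_preceding_minimum(self):
        bp, _ = pulse_train()
        beats = detect_beats(bp)
        for row in beats.itertuples():
            assert row.onset < row.peak
            assert bp.samples[int(row.onset)] <= bp.samples[int(row.peak)] - 20


def make_separated_fixture(rho=0.3, rate=250.0, duration=20.0, f0=3.0):
    """Hand-built IMFSet with known forward/riding components (no EEMD)."""
    t = np.arange(0, duration, 1 / rate)
    pf = 30.0
    forward = pf * 0.5 * (1 - np.cos(2 * np.pi * f0 * t))  # peaks where cos=−1
    pb = rho / (1 - rho) * pf
    # riding crest aligned with the forward peaks (forward peaks at odd k/2f0)
    riding = (pb / 2) * np.cos(2 * np.pi * 2 * f0 * (t - 0.5 / f0))
    slow = 2.0 * np.sin(2 * np.pi * 0.2 * t)
    imfs = np.vstack([riding, forward - forward.mean(), slow])
    iset = IMFSet(imfs, np.full(t.size, forward.mean()), rate, "eemd")
    ver = MCVerification(
        energies=np.array([np.mean(r**2) for r in imfs]),
        periods=np.array([1 / (2 * f0), 1 / f0, 5.0]),
        flags=("signal", "signal", "signal"),
        noise_log_offset=0.0,
        reference=None,
    )
    return iset, ver, forward, riding, pb, pf


class TestSeparateWaves:
    def test_riding_selection_and_partition(self):
        iset, ver, forward, riding, pb, pf = make_separated_fixture()
        fwd, rid, idx = separate_waves(iset, ver, 3.0)
        assert idx == 0
        assert np.corrcoef(rid.samples, riding)[0, 1] > 0.9
        total = iset.imfs[[0, 1, 2]].sum(axis=0)
        np.testing.assert_allclose(fwd.samples + rid.samples, total, atol=1e-12)

    def test_riding_has_two_peaks_per_beat(self):
        from scipy.signal import find_peaks

        iset, ver, *_ = make_separated_fixture(duration=20.0)
        _, rid, _ = separate_waves(iset, ver, 3.0)
        n_beats = 20.0 * 3.0
        peaks, _ = find_peaks(rid.samples)
        assert abs(peaks.size - 2 * n_beats) <= 0.1 * 2 * n_beats

    def test_no_candidate_raises(self):
        t = np.arange(0, 10, 1 / 100)
        imfs = np.vstack([np.sin(2 * np.pi * 0.2 * t), np.sin(2 * np.pi * 0.1 * t)])
        iset = IMFSet(imfs, np.zeros(t.size), 100.0, "eemd")
        ver = MCVerification(
            energies=np.array([0.5, 0.5]),
            periods=np.array([5.0, 10.0]),
            flags=("signal", "signal"),
            noise_log_offset=0.0,
            reference=None,
        )
        with pytest.raises(SeparationError):
            separate_waves(iset, ver, 3.0)


class TestBeatAmplitudes:
    def test_recovers_constructed_amplitudes(self):
        iset, ver, forward, riding, pb, pf = make_separated_fixture(rho=0.3)
        bp = Signal(iset.reconstruct(), iset.rate)
        beats = detect_beats(bp)
        fwd, rid, _ = separate_waves(iset, ver, 3.0)
        table = beat_amplitudes(fwd, rid, beats)
        inner = table.iloc[1:-1]
        assert inner["pf"].median() == pytest.approx(pf, rel=0.02)
        assert inner["pb"].median() == pytest.approx(pb, rel=0.05)
        assert inner["ri_eemd"].median() == pytest.approx(0.3, abs=0.02)

    def test_zero_riding_gives_zero_ri(self):
        iset, ver, forward, *_ = make_separated_fixture()
        bp = Signal(iset.reconstruct(), iset.rate)
        beats = detect_beats(bp)
        fwd = Signal(forward - forward.mean(), iset.rate)
        zero = Signal(np.zeros(forward.size), iset.rate)
        table = beat_amplitudes(fwd, zero, beats)
        assert (table["pb"].dropna() == 0).all()
        assert (table["ri_eemd"].dropna() == 0).all()


class TestReflectionIndex:
    @pytest.mark.parametrize(
        "pb,pf,expected", [(1.0, 1.0, 0.5), (0.0, 5.0, 0.0), (1.0, 3.0, 0.25)]
    )
    def test_values(self, pb, pf, expected):
        assert reflection_index(pb, pf) == pytest.approx(expected)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            reflection_index(-0.1, 1.0)
        with pytest.raises(ValueError):
            reflection_index(1.0, 0.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        pf=st.floats(min_value=0.5, max_value=100.0),
        pb1=st.floats(min_value=0.0, max_value=100.0),
        delta=st.floats(min_value=0.01, max_value=10.0),
    )
    def test_monotone_in_pb(self, pf, pb1, delta):
        assert reflection_index(pb1 + delta, pf) > reflection_index(pb1, pf)


class TestReferredRI:
    def test_linear_upstroke_is_exact(self):
        # linear rise onset->peak over exactly the ejection time: the 30%
        # inflection splits pf:pb as 0.3:0.7, RI = 0.7
        rate = 1000.0
        beat = np.concatenate([np.linspace(0, 30, 300), np.linspace(30, 0, 700)[1:]])
        x = 70 + np.tile(beat, 12)
        bp = Signal(x, rate)
        beats = detect_beats(bp, min_rate=0.5, max_rate=2.0)
        et = np.full(len(beats), 0.3)  # time-to-peak as ejection time
        table = referred_ri(bp, beats, ejection_time=et)
        inner = table["ri_referred"].iloc[1:-1]
        assert np.allclose(inner, 0.7, atol=0.01)

    def test_peak_at_inflection_gives_zero(self):
        rate = 1000.0
        # peak reached at 30% of the stated ejection time, flat afterwards
        beat = np.concatenate(
            [np.linspace(0, 30, 150), np.full(350, 30.0), np.linspace(30, 0, 500)]
        )
        bp = Signal(70 + np.tile(beat, 12), rate)
        beats = detect_beats(bp, min_rate=0.5, max_rate=2.0)
        table = referred_ri(bp, beats, ejection_time=np.full(len(beats), 0.5))
        inner = table["ri_referred"].iloc[1:-1].dropna()
        assert (inner <= 0.02).all()

    def test_nonpositive_ejection_time_skipped(self):
        bp, _ = pulse_train()
        beats = detect_beats(bp)
        table = referred_ri(bp, beats, ejection_time=np.zeros(len(beats)))
        assert table["ri_referred"].isna().all()


class TestMovingAverage:
    def test_window_one_is_identity(self):
        x = np.arange(10.0)
        np.testing.assert_array_equal(moving_average(x, 1), x)

    def test_constant_unchanged(self):
        np.testing.assert_allclose(moving_average(np.full(20, 3.0), 5), 3.0)

    def test_alternating_interior(self):
        x = np.array([1.0, -1, 1, -1, 1, -1, 1])
        out = moving_average(x, 3)
        np.testing.assert_allclose(out[1:-1], [1 / 3, -1 / 3, 1 / 3, -1 / 3, 1 / 3])

    def test_even_or_long_window_rejected(self):
        with pytest.raises(ValueError):
            moving_average(np.arange(10.0), 4)
        with pytest.raises(ValueError):
            moving_average(np.arange(5.0), 7)


class TestCyclicPeriod:
    def test_respiratory_modulation_period(self):
        # per-beat SAP at ~3 Hz beats modulated at 0.34 Hz over 60 s
        t = np.arange(0, 60, 1 / 3.0)
        sap = 120 + 3 * np.sin(2 * np.pi * 0.34 * t) + 0.1 * t  # slow trend too
        period = cyclic_period(sap, t)
        assert period == pytest.approx(1 / 0.34, abs=0.15)

    def test_constant_series_undefined(self):
        t = np.arange(0, 30, 1 / 3.0)
        with pytest.raises(ValueError):
            cyclic_period(np.full(t.size, 120.0), t)

    def test_crossings_match_brute_force(self):
        rng = np.random.default_rng(9)
        t = np.arange(0, 40, 1 / 3.0)
        y = np.sin(2 * np.pi * 0.3 * t) + 0.1 * rng.standard_normal(t.size)
        detrended = y - moving_average(y, 9)
        pos = detrended > 0
        expected = int(np.count_nonzero(~pos[:-1] & pos[1:]))
        # reconstruct crossing count from the returned period
        period = cyclic_period(y, t)
        pos_idx = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
        assert period == pytest.approx(
            (t[pos_idx[-1]] - t[pos_idx[0]]) / (expected - 1)
        )
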