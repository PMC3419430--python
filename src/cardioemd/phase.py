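"""ECG-BP cardiac-oscillation phase shift and pulse transit time.

The ECG is treated as the driving signal of the cardiovascular system and
arterial BP as its output; the systemic impedance then shows up as a phase
delay between the *cardiac oscillations* — the IMF of each channel whose
averaged frequency matches the heart rate.  The Hilbert transform supplies
each cardiac IMF's instantaneous phase; unwrapping gives the accumulative
phase, and the per-sample difference of the two accumulative phases is the
phase shift.  Sign convention: ``shift = phase_ecg - phase_bp``, so a BP
wave lagging the ECG gives a positive shift (a pure delay of ``tau`` at
carrier frequency ``f`` gives ``2*pi*f*tau``).

Pulse transit time (PTT) — the delay between each ECG R peak and the next
systolic BP peak — is computed alongside for comparison; the phase shift
roughly equals ``2*pi * PTT / beat interval``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks, hilbert

from .eemd import average_frequency
from .emd import IMFSet
from .reflection import moving_average
from .signal import Signal

DEFAULT_SHIFT_WINDOW = 100  # samples, ~10 Hz equivalent cutoff at 1000 Hz
CARDIAC_RATIO_BAND = (0.6, 1.67)


class NoCardiacIMFError(ValueError):
    """No IMF with averaged frequency close enough to the heart rate."""


def select_cardiac_imf(imfset: IMFSet, heart_rate_hz: float) -> int:
    """Index of the IMF representing the cardiac oscillation.

    Chooses the IMF whose averaged (zero-crossing) frequency is nearest
    ``heart_rate_hz``; the winner's frequency-to-heart-rate ratio must lie
    in ``[0.6, 1.67]``.
    """
    best, best_dist = None, np.inf
    for i in range(imfset.n_imfs):
        try:
            f = average_frequency(imfset.imfs[i], imfset.rate, "zero-crossing")
        except ValueError:
            continue
        if f <= 0:
            continue
        ratio = f / heart_rate_hz
        if not (CARDIAC_RATIO_BAND[0] <= ratio <= CARDIAC_RATIO_BAND[1]):
            continue
        dist = abs(np.log(ratio))
        if dist < best_dist:
            best, best_dist = i, dist
    if best is None:
        raise NoCardiacIMFError(
            f"no IMF with averaged frequency within "
            f"[{CARDIAC_RATIO_BAND[0]:.2f}, {CARDIAC_RATIO_BAND[1]:.2f}] "
            f"x {heart_rate_hz:.2f} Hz"
        )
    return best


def hilbert_phase(imf: np.ndarray, rate: float | None = None) -> np.ndarray:
    """Instantaneous phase of an oscillatory sequence, wrapped to (-pi, pi].

    The phase is the angle of the analytic signal (the sequence plus i
    times its Hilbert-transform quadrature).  Expects a zero-mean
    oscillation; an all-zero input has no phase.
    """
    imf = np.asarray(imf, dtype=float)
    if not np.any(imf != 0):
        raise ValueError("phase undefined for an all-zero sequence")
    return np.angle(hilbert(imf))


def cumulative_phase(phase: np.ndarray) -> np.ndarray:
    """Unwrap a wrapped phase sequence into an accumulative phase.

    Adds multiples of 2*pi at jumps larger than pi so that sustained
    oscillation yields a (numerically) nondecreasing phase; the first
    sample keeps its wrapped value.
    """
    return np.unwrap(np.asarray(phase, dtype=float))


@dataclass(frozen=True)
class PhaseShiftSeries:
    """Per-sample accumulative phases of the two cardiac oscillations.

    ``shift = phase_ecg - phase_bp`` (positive = BP lags ECG);
    ``shift_smoothed`` is the centered moving-average of ``shift``.
    """

    time: np.ndarray
    phase_ecg: np.ndarray
    phase_bp: np.ndarray
    shift: np.ndarray
    shift_smoothed: np.ndarray
    rate: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time,
                "phase_ecg": self.phase_ecg,
                "phase_bp": self.phase_bp,
                "shift": self.shift,
                "shift_smoothed": self.shift_smoothed,
            }
        )


def phase_shift(
    ecg_cardiac: np.ndarray,
    bp_cardiac: np.ndarray,
    rate: float,
    smooth_window: int = DEFAULT_SHIFT_WINDOW,
) -> PhaseShiftSeries:
    """Accumulative-phase difference between two cardiac oscillations.

    Both inputs must be equal-length cardiac IMFs from synchronized
    recordings.  The shift is smoothed with a centered moving average of
    ``smooth_window`` samples (even values are rounded up to the next odd
    number; the default 100 matches a ~10 Hz equivalent cutoff at 1000 Hz).
    """
    ecg_cardiac = np.asarray(ecg_cardiac, dtype=float)
    bp_cardiac = np.asarray(bp_cardiac, dtype=float)
    if ecg_cardiac.size != bp_cardiac.size:
        raise ValueError("cardiac IMFs must have equal length")
    phi_e = cumulative_phase(hilbert_phase(ecg_cardiac))
    phi_b = cumulative_phase(hilbert_phase(bp_cardiac))
    shift = phi_e - phi_b
    w = min(smooth_window, shift.size)
    if w % 2 == 0:
        w += 1 if w < shift.size else -1
    smoothed = moving_average(shift, max(w, 1))
    n = ecg_cardiac.size
    return PhaseShiftSeries(
        time=np.arange(n) / rate,
        phase_ecg=phi_e,
        phase_bp=phi_b,
        shift=shift,
        shift_smoothed=smoothed,
        rate=rate,
    )


def detect_r_peaks(
    ecg_cardiac: Signal,
    heart_rate_hz: float,
    raw_ecg: Signal | None = None,
    refine_window_s: float = 0.04,
) -> np.ndarray:
    """R-peak sample indices from the cardiac-band ECG reconstruction.

    Peaks of the cardiac IMF mark the R points.  When the raw ECG is
    supplied, each candidate is snapped to the raw-signal maximum within
    ``refine_window_s`` seconds, which removes the small phase bias the
    P and T waves impose on the cardiac-band component.
    """
    x = ecg_cardiac.samples
    distance = max(1, int(round(0.6 * ecg_cardiac.rate / heart_rate_hz)))
    prom = 0.5 * float(np.std(x))
    peaks, _ = find_peaks(x, distance=distance, prominence=prom)
    if raw_ecg is not None and peaks.size:
        half = int(round(refine_window_s * ecg_cardiac.rate))
        refined = []
        for p in peaks:
            lo, hi = max(0, p - half), min(raw_ecg.n, p + half + 1)
            refined.append(lo + int(np.argmax(raw_ecg.samples[lo:hi])))
        peaks = np.asarray(refined)
    return peaks


def pulse_transit_time(
    ecg_cardiac: Signal,
    beats: pd.DataFrame,
    heart_rate_hz: float,
    raw_ecg: Signal | None = None,
) -> pd.DataFrame:
    """Per-beat pulse transit time: systolic-peak time minus preceding R time.

    R peaks come from :func:`detect_r_peaks` on the ECG cardiac-band
    reconstruction (optionally refined against the raw ECG); each beat's
    systolic peak is matched with the nearest preceding R peak and beats
    without one (or with a non-positive delay) are skipped (``NaN``).

    Returns a copy of ``beats`` with a ``ptt`` column in seconds.
    """
    r_peaks = detect_r_peaks(ecg_cardiac, heart_rate_hz, raw_ecg=raw_ecg)
    out = beats.copy()
    ptt = np.full(len(beats), np.nan)
    if r_peaks.size:
        sys_peaks = beats["peak"].to_numpy()
        pos = np.searchsorted(r_peaks, sys_peaks, side="left") - 1
        valid = pos >= 0
        delays = np.where(valid, sys_peaks - r_peaks[np.clip(pos, 0, None)], -1)
        good = valid & (delays > 0)
        ptt[good] = delays[good] / ecg_cardiac.rate
    out["ptt"] = ptt
    return out
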