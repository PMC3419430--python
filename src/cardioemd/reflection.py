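"""Beat segmentation and arterial wave-reflection indexes.

The reflection index ``RI = Pb / (Pb + Pf)`` quantifies the reflected
pressure wave's share of the total pulse magnitude and rises with arterial
stiffness.  Two estimators are provided:

* **Decomposition-based RI** — the verified IMFs of the BP recording are
  split into a *forward* wave (the cardiac-band components following the
  heartbeat rhythm) and a *riding* component oscillating at twice the
  cardiac rate, which carries the reflected wave (peaking with systole) and
  the dicrotic wave (after valve closure).  Per beat, ``Pf`` is the
  peak-to-trough excursion of the forward wave and ``Pb`` the
  peak-to-trough amplitude of the riding oscillation that coincides with
  the systolic peak.
* **Referred (triangular) RI** — the aortic flow pulse is approximated by a
  triangle of duration equal to the ejection time, which places the
  pressure inflection point at 30% of the ejection time after the foot of
  the beat; ``Pf`` is the pressure rise up to the inflection point and
  ``Pb`` the secondary rise from there to the systolic peak.  This needs
  the BP channel only and serves as the reference algorithm.

Per-beat series are smoothed with a centered moving average (default 9
beats ≈ one respiratory cycle at a 3 Hz heart rate and ~0.34 Hz
respiration) before cross-index correlation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .eemd import average_frequency
from .emd import IMFSet
from .significance import MCVerification
from .signal import Signal

DEFAULT_RI_WINDOW = 9
DEFAULT_PROMINENCE_FRACTION = 0.3


class NoBeatsError(ValueError):
    """No systolic peaks satisfying the rate constraints were found."""


class SeparationError(ValueError):
    """No IMF close enough to twice the cardiac frequency."""


def detect_beats(
    bp: Signal,
    min_rate: float = 1.0,
    max_rate: float = 5.0,
    prominence_fraction: float = DEFAULT_PROMINENCE_FRACTION,
) -> pd.DataFrame:
    """Locate systolic peaks and beat onsets in a BP waveform.

    Systolic peaks are found by prominence-based peak detection with the
    inter-peak distance constrained to ``[1/max_rate, 1/min_rate]``
    seconds; the required prominence is ``prominence_fraction`` of the
    5th-95th percentile span.  Each beat's onset is the diastolic minimum
    preceding its systolic peak.

    Returns
    -------
    DataFrame with one row per beat: ``onset``, ``peak`` (sample indices),
    ``t_onset``, ``t_peak`` (seconds), ``sap`` (peak value, signal units).

    Raises
    ------
    NoBeatsError
        When no peaks satisfy the constraints (e.g. constant input).
    """
    x = bp.samples
    span = float(np.percentile(x, 95) - np.percentile(x, 5))
    if span <= 0:
        raise NoBeatsError("signal has no amplitude variation")
    distance = max(1, int(round(bp.rate / max_rate)))
    peaks, _ = find_peaks(x, distance=distance, prominence=prominence_fraction * span)
    if peaks.size < 1:
        raise NoBeatsError("no systolic peaks under the rate constraints")

    max_interval = int(round(bp.rate / min_rate))
    onsets = np.empty_like(peaks)
    for i, p in enumerate(peaks):
        lo = peaks[i - 1] if i > 0 else max(0, p - max_interval)
        seg = x[lo:p] if p > lo else x[p : p + 1]
        onsets[i] = lo + int(np.argmin(seg)) if seg.size else p
    return pd.DataFrame(
        {
            "onset": onsets,
            "peak": peaks,
            "t_onset": onsets / bp.rate,
            "t_peak": peaks / bp.rate,
            "sap": x[peaks],
        }
    )


def _beat_bounds(beats: pd.DataFrame, n: int) -> list[tuple[int, int]]:
    onsets = beats["onset"].to_numpy()
    ends = np.append(onsets[1:], n)
    return list(zip(onsets, ends))


def separate_waves(
    imfset: IMFSet,
    verification: MCVerification,
    cardiac_hz: float,
) -> tuple[Signal, Signal, int]:
    """Split the verified decomposition into forward and riding waves.

    The riding component (reflected + dicrotic waves) is the signal-flagged
    IMF whose averaged frequency is nearest twice the cardiac frequency; the
    forward wave is the sum of the remaining signal-flagged IMFs, so
    ``forward + riding`` equals the noise-removed reconstruction exactly.
    The IMF carrying the cardiac oscillation itself (averaged frequency
    nearest ``cardiac_hz``) is never eligible: when the reflected wave is
    too weak to form its own mode, the cardiac IMF would otherwise slip
    into the acceptance band and masquerade as the riding wave.

    Returns ``(forward, riding, riding_index)`` with the selected IMF index
    recorded for audit.

    Raises
    ------
    SeparationError
        If no signal-flagged IMF lies within +/-50% of ``2 * cardiac_hz``.
    """
    target = 2.0 * cardiac_hz
    sig_idx = verification.signal_indices
    if sig_idx.size < 2:
        raise SeparationError("need at least two signal-flagged IMFs")
    freqs = {}
    for i in sig_idx:
        try:
            # power-weighted centroid: robust to spurious zero crossings in
            # the quiet stretches of an amplitude-modulated IMF
            freqs[i] = average_frequency(
                imfset.imfs[i], imfset.rate, "spectral-centroid"
            )
        except ValueError:
            continue
    if not freqs:
        raise SeparationError("no signal IMF with a defined averaged frequency")
    cardiac_idx = min(
        freqs, key=lambda i: abs(np.log(freqs[i] / cardiac_hz)) if freqs[i] > 0 else np.inf
    )
    candidates = {
        i: f
        for i, f in freqs.items()
        if i != cardiac_idx and abs(f / target - 1.0) <= 0.5
    }
    if not candidates:
        raise SeparationError(
            f"no signal IMF within 50% of twice the cardiac rate ({target:.2f} Hz)"
        )
    riding_index = min(candidates, key=lambda i: abs(np.log(candidates[i] / target)))
    forward_idx = [i for i in sig_idx if i != riding_index]
    forward = imfset.imfs[forward_idx].sum(axis=0)
    riding = imfset.imfs[riding_index]
    return (
        Signal(forward, imfset.rate, "forward"),
        Signal(riding, imfset.rate, "riding"),
        int(riding_index),
    )


def beat_amplitudes(
    forward: Signal,
    riding: Signal,
    beats: pd.DataFrame,
) -> pd.DataFrame:
    """Per-beat forward (Pf) and reflected (Pb) wave magnitudes and RI.

    ``Pf`` is the max-minus-min excursion of the forward wave within the
    beat.  ``Pb`` is the peak-to-trough swing of the riding oscillation
    that accompanies the systolic peak: among the riding component's local
    peaks in the beat, the one nearest the systolic peak (within a quarter
    beat) is taken, and its amplitude is measured down to the following
    trough.  The later, dicrotic riding peak is excluded.  Beats without a
    systolic-coincident riding peak get ``Pb = NaN`` and are excluded from
    downstream correlations.

    Returns a copy of ``beats`` with columns ``pf``, ``pb``, ``ri_eemd``.
    """
    if forward.n != riding.n:
        raise ValueError("forward and riding waves must share length")
    fw, rd = forward.samples, riding.samples
    out = beats.copy()
    pf_col = np.full(len(beats), np.nan)
    pb_col = np.full(len(beats), np.nan)
    ri_col = np.full(len(beats), np.nan)
    bounds = _beat_bounds(beats, forward.n)
    peaks = beats["peak"].to_numpy()
    for k, (lo, hi) in enumerate(bounds):
        if hi - lo < 3:
            continue
        seg_f = fw[lo:hi]
        pf = float(seg_f.max() - seg_f.min())
        pf_col[k] = pf
        seg_r = rd[lo:hi]
        if not np.any(seg_r != 0):
            pb_col[k] = 0.0
            ri_col[k] = 0.0 if pf > 0 else np.nan
            continue
        rpeaks, _ = find_peaks(seg_r)
        if rpeaks.size == 0:
            continue
        sys_rel = peaks[k] - lo
        quarter = 0.25 * (hi - lo)
        near = rpeaks[np.abs(rpeaks - sys_rel) <= quarter]
        if near.size == 0:
            continue
        rp = near[np.argmin(np.abs(near - sys_rel))]
        later = rpeaks[rpeaks > rp]
        trough_hi = later[0] if later.size else seg_r.size
        trough = float(seg_r[rp:trough_hi].min()) if trough_hi > rp else float(seg_r[rp])
        pb = float(seg_r[rp]) - trough
        pb_col[k] = pb
        if pb + pf > 0:
            ri_col[k] = reflection_index(pb, pf)
    out["pf"] = pf_col
    out["pb"] = pb_col
    out["ri_eemd"] = ri_col
    return out


def reflection_index(pb: float, pf: float) -> float:
    """``RI = Pb / (Pb + Pf)``, the reflected wave's share of the pulse.

    Requires ``Pf > 0`` and ``Pb >= 0``; lies in ``[0, 1)``.
    """
    if pb < 0 or pf <= 0:
        raise ValueError("need Pb >= 0 and Pf > 0")
    total = pb + pf
    if total == 0:
        raise ValueError("Pb + Pf = 0; RI undefined")
    return pb / total


def referred_ri(
    bp: Signal,
    beats: pd.DataFrame,
    riding: Signal | None = None,
    ejection_time: np.ndarray | None = None,
    peak_delay_fallback: float = 0.1,
) -> pd.DataFrame:
    """Triangular (30%-of-ejection-time) reflection index, per beat.

    The inflection point separating forward and reflected contributions is
    placed at 30% of the ejection time after the beat onset.  Per beat,
    ``Pf = BP(inflection) - BP(onset)`` and ``Pb = SAP - BP(inflection)``
    (the secondary rise, floored at 0); ``RI = Pb / (Pb + Pf)``.

    Ejection time per beat is, in order of preference: the ``ejection_time``
    array when supplied; onset-to-dicrotic-notch, the notch being the
    minimum of the ``riding`` component after the systolic peak; else
    onset-to-(systolic peak + ``peak_delay_fallback`` seconds).  Beats with
    non-positive ejection time or a degenerate upstroke are skipped (NaN).

    Returns a copy of ``beats`` with ``ejection_time`` and ``ri_referred``.
    """
    x = bp.samples
    out = beats.copy()
    n = x.size
    bounds = _beat_bounds(beats, n)
    onsets = beats["onset"].to_numpy()
    peaks = beats["peak"].to_numpy()
    et_col = np.full(len(beats), np.nan)
    ri_col = np.full(len(beats), np.nan)
    for k, (lo, hi) in enumerate(bounds):
        if ejection_time is not None:
            et = float(ejection_time[k])
        elif riding is not None and peaks[k] + 1 < hi:
            seg = riding.samples[peaks[k] : hi]
            notch = peaks[k] + int(np.argmin(seg))
            et = (notch - onsets[k]) / bp.rate
        else:
            et = (peaks[k] - onsets[k]) / bp.rate + peak_delay_fallback
        if et <= 0:
            continue
        et_col[k] = et
        infl = onsets[k] + int(round(0.30 * et * bp.rate))
        if infl >= n:
            continue
        pf = float(x[infl] - x[onsets[k]])
        if pf <= 0:
            continue
        pb = max(float(x[peaks[k]] - x[infl]), 0.0)
        ri_col[k] = reflection_index(pb, pf)
    out["ejection_time"] = et_col
    out["ri_referred"] = ri_col
    return out


def moving_average(series: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges.

    ``window`` must be odd and no longer than the series; length is
    preserved and a window of 1 is the identity.
    """
    series = np.asarray(series, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if window > series.size:
        raise ValueError("window longer than the series")
    half = window // 2
    csum = np.cumsum(np.concatenate(([0.0], series)))
    n = series.size
    idx = np.arange(n)
    lo = np.maximum(idx - half, 0)
    hi = np.minimum(idx + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def cyclic_period(
    per_beat_series: np.ndarray,
    beat_times: np.ndarray,
    detrend_window: int = DEFAULT_RI_WINDOW,
) -> float:
    """Average period of the cyclic (respiratory) swing of a per-beat series.

    The series is detrended by subtracting a centered moving average
    (default 9 beats, ≈ one respiratory cycle), ascending zero crossings of
    the detrended series are counted as cycle starts, and the period is the
    time span between the first and last crossing divided by the number of
    full cycles between them.

    Raises
    ------
    ValueError
        With fewer than two ascending crossings the period is undefined.
    """
    y = np.asarray(per_beat_series, dtype=float)
    t = np.asarray(beat_times, dtype=float)
    if y.size != t.size:
        raise ValueError("series and beat_times must have equal length")
    w = min(detrend_window, y.size if y.size % 2 else y.size - 1)
    detrended = y - moving_average(y, w)
    pos = detrended > 0
    ascend = np.flatnonzero(~pos[:-1] & pos[1:]) + 1
    if ascend.size < 2:
        raise ValueError("fewer than two mean crossings; cyclic period undefined")
    return float((t[ascend[-1]] - t[ascend[0]]) / (ascend.size - 1))
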