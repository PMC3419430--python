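"""Monte-Carlo verification of noisy IMFs and noise-removed reconstruction.

For white noise decomposed by EMD, the points (ln averaged-period,
ln energy-density) of successive IMFs fall on a straight line with negative
slope in the log-log plane.  Simulating many white-noise decompositions
traces an empirical confidence band around that line; an IMF of a real
signal whose point falls inside the band is indistinguishable from noise,
while a dominant physiological component rises far above it.

Definitions (per IMF ``C_n`` of ``N`` samples):

* energy density ``E_n = mean(C_n ** 2)``
* averaged period ``T_n = (sum_k S_k) / (sum_k S_k * f_k)`` over positive
  frequencies ``f_k`` of the magnitude-squared Fourier spectrum ``S`` — the
  discrete form of the spectrum-weighted mean period (the reciprocal of the
  spectral-centroid frequency).

Classification scales the band to the signal's own noise level by anchoring
on the first IMF, which in a noisy recording is essentially pure noise: the
observed ``ln E_1`` is compared with the reference's mean first-order noise
energy, and the whole band is shifted by the difference.  The leading
contiguous run of IMFs inside the shifted band is flagged ``noise``; the
run stops at the first IMF outside it.  IMFs whose averaged period exceeds
a quarter of the record length are ``trend`` (too few cycles to judge);
everything else is ``signal``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .emd import IMFSet, emd
from .signal import Signal

TREND_PERIOD_FRACTION = 0.25


def energy_density(imf: np.ndarray) -> float:
    """Mean squared sample of an IMF. Empty input is invalid."""
    imf = np.asarray(imf, dtype=float)
    if imf.size == 0:
        raise ValueError("energy density undefined for an empty sequence")
    return float(np.mean(imf**2))


def averaged_period(imf: np.ndarray, rate: float) -> float:
    """Spectrum-weighted mean period of an IMF, in seconds.

    Computed as ``(sum S_k) / (sum S_k * f_k)`` with ``S`` the
    magnitude-squared Fourier spectrum over positive frequencies, i.e. the
    reciprocal of the spectral-centroid frequency.

    Raises
    ------
    ValueError
        When the positive-frequency spectral mass is zero (constant
        sequence), leaving the period undefined.
    """
    imf = np.asarray(imf, dtype=float)
    spec = np.abs(np.fft.rfft(imf)) ** 2
    freqs = np.fft.rfftfreq(imf.size, d=1.0 / rate)
    power = spec[1:]
    weighted = float((power * freqs[1:]).sum())
    if weighted == 0.0:
        raise ValueError("zero spectral mass; averaged period undefined")
    return float(power.sum() / weighted)


@dataclass(frozen=True)
class WhiteNoiseReference:
    """Empirical white-noise band in the (ln period, ln energy) plane.

    ``slope``/``intercept`` give the least-squares line through the pooled
    Monte-Carlo points; ``resid_lo``/``resid_hi`` are residual percentiles
    bounding the band; ``anchor_log_e1`` is the mean ln energy of
    first-order IMFs, used to rescale the band to a signal's noise level.
    Periods are in samples (rate-free).
    """

    slope: float
    intercept: float
    resid_lo: float
    resid_hi: float
    anchor_log_e1: float
    n_samples: int
    n_realizations: int
    confidence: tuple[float, float]
    points: np.ndarray = field(repr=False)  # (n_points, 3): order, lnT, lnE

    def line(self, log_period: np.ndarray | float) -> np.ndarray | float:
        return self.intercept + self.slope * np.asarray(log_period, dtype=float)

    def band(self, log_period: np.ndarray | float) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) ln-energy bounds at the given ln period(s)."""
        center = self.line(log_period)
        return center + self.resid_lo, center + self.resid_hi


def white_noise_reference(
    n_samples: int = 4096,
    n_realizations: int = 100,
    confidence: tuple[float, float] = (1.0, 99.0),
    seed: int = 0,
    max_imfs: int = 12,
) -> WhiteNoiseReference:
    """Build the white-noise confidence band by Monte-Carlo simulation.

    Decomposes ``n_realizations`` unit-variance Gaussian white-noise
    sequences of ``n_samples`` with plain EMD, pools the per-IMF
    (ln averaged-period, ln energy-density) points, fits a straight line
    and takes the ``confidence`` percentiles of its residuals as the band.
    Deterministic given ``seed``.
    """
    if n_realizations < 50:
        raise ValueError("need at least 50 realizations for a stable band")
    streams = np.random.SeedSequence(seed).spawn(n_realizations)
    rows = []
    for ss in streams:
        rng = np.random.default_rng(ss)
        dec = emd(Signal(rng.standard_normal(n_samples), 1.0), max_imfs=max_imfs)
        if dec.n_imfs < 3:
            raise ValueError("n_samples too short to yield at least 3 IMFs")
        for order, imf in enumerate(dec.imfs, start=1):
            e = energy_density(imf)
            if e == 0.0:
                continue
            t = averaged_period(imf, 1.0)
            rows.append((order, np.log(t), np.log(e)))
    points = np.array(rows)
    log_t, log_e = points[:, 1], points[:, 2]
    slope, intercept = np.polyfit(log_t, log_e, 1)
    resid = log_e - (intercept + slope * log_t)
    lo, hi = np.percentile(resid, confidence)
    anchor = float(points[points[:, 0] == 1, 2].mean())
    return WhiteNoiseReference(
        slope=float(slope),
        intercept=float(intercept),
        resid_lo=float(lo),
        resid_hi=float(hi),
        anchor_log_e1=anchor,
        n_samples=n_samples,
        n_realizations=n_realizations,
        confidence=confidence,
        points=points,
    )


@dataclass(frozen=True)
class MCVerification:
    """Per-IMF Monte-Carlo verification result.

    ``flags`` holds exactly one of ``"noise"``, ``"signal"`` or ``"trend"``
    per IMF; ``energies`` are energy densities in squared signal units and
    ``periods`` averaged periods in seconds.  ``noise_log_offset`` is the
    vertical band shift applied to match the signal's estimated noise level.
    """

    energies: np.ndarray
    periods: np.ndarray
    flags: tuple[str, ...]
    noise_log_offset: float
    reference: WhiteNoiseReference

    @property
    def noise_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.flags) == "noise")

    @property
    def signal_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.flags) == "signal")

    @property
    def trend_indices(self) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.flags) == "trend")

    def to_dict(self) -> dict:
        return {
            "energy_density": self.energies.tolist(),
            "averaged_period_s": self.periods.tolist(),
            "flags": list(self.flags),
            "noise_log_offset": self.noise_log_offset,
            "band": {
                "slope": self.reference.slope,
                "intercept": self.reference.intercept,
                "resid_lo": self.reference.resid_lo,
                "resid_hi": self.reference.resid_hi,
                "confidence": list(self.reference.confidence),
                "n_samples": self.reference.n_samples,
                "n_realizations": self.reference.n_realizations,
            },
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def classify_imfs(imfset: IMFSet, ref: WhiteNoiseReference) -> MCVerification:
    """Flag each IMF of a decomposition as noise, signal or trend.

    The reference band (built for unit-variance noise) is shifted
    vertically so its first-order mean energy matches the observed first
    IMF — the first IMF of a noisy recording is taken as (almost) pure
    noise.  The leading contiguous run of IMFs whose point lies inside the
    shifted band is noise; IMFs with averaged period longer than a quarter
    of the record are trend; the rest are signal.
    """
    if imfset.n_imfs == 0:
        raise ValueError("cannot classify an empty IMF set")
    energies = np.array([energy_density(imf) for imf in imfset.imfs])
    periods = np.empty(imfset.n_imfs)
    for i, imf in enumerate(imfset.imfs):
        try:
            periods[i] = averaged_period(imf, imfset.rate)
        except ValueError:
            periods[i] = np.inf

    duration = imfset.n_samples / imfset.rate
    trend = periods > TREND_PERIOD_FRACTION * duration

    # vertical band shift: observed ln E_1 vs reference first-order energy
    offset = (
        float(np.log(energies[0]) - ref.anchor_log_e1) if energies[0] > 0 else 0.0
    )
    with np.errstate(divide="ignore"):
        log_e = np.log(energies)
    log_t_samples = np.log(periods * imfset.rate)  # reference periods are in samples
    lo, hi = ref.band(log_t_samples)
    inside = np.isfinite(log_e) & (log_e - offset >= lo) & (log_e - offset <= hi)

    flags = []
    in_leading_run = True
    for i in range(imfset.n_imfs):
        if trend[i]:
            flags.append("trend")
            in_leading_run = False
        elif in_leading_run and inside[i]:
            flags.append("noise")
        else:
            flags.append("signal")
            in_leading_run = False
    return MCVerification(
        energies=energies,
        periods=periods,
        flags=tuple(flags),
        noise_log_offset=offset,
        reference=ref,
    )


def denoise(
    imfset: IMFSet, verification: MCVerification, drop_trend: bool = True
) -> Signal:
    """Noise-removed reconstruction from the verified decomposition.

    Sums the signal-flagged IMFs; with ``drop_trend=False`` the trend-like
    IMFs and the residue are added back as well (so that, when everything
    is signal-flagged, the full completeness sum is returned).  Noise IMFs
    are always excluded.

    Raises
    ------
    ValueError
        If no IMF is signal-flagged (empty reconstruction).
    """
    sig_idx = verification.signal_indices
    if sig_idx.size == 0:
        raise ValueError("no signal-flagged IMFs; reconstruction would be empty")
    out = imfset.imfs[sig_idx].sum(axis=0)
    if not drop_trend:
        trend_idx = verification.trend_indices
        if trend_idx.size:
            out = out + imfset.imfs[trend_idx].sum(axis=0)
        out = out + imfset.residue
    return Signal(out, imfset.rate, "denoised")
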