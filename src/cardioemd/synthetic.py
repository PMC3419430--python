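"""Synthetic pig ECG/BP generator with full ground truth.

Emulates the kind of recording the toolkit targets: synchronized ECG and
femoral blood pressure from an anesthetized young pig whose intestinal
artery is alternately clamped and relaxed, driving systolic pressure up to
a plateau and back down.  Defaults follow that setting: 1000 Hz sampling,
~3.1 Hz heart rate, ~0.34 Hz respiratory modulation, a
clamp-relax-clamp-relax protocol of four one-minute phases (240 s total),
BP pulses built from a smooth forward wave plus a riding component at twice
the cardiac rate carrying the reflected wave (peaking with systole) and the
dicrotic wave (after it), white measurement noise at 20 dB SNR and a slow
baseline drift.

The physiological couplings are linear with configurable gains so that the
expected correlation pattern is known by construction: the reflection ratio
``rho = Pb / (Pb + Pf)`` increases with SAP (stiffening under pressure) and
the R-to-systolic delay ``tau`` decreases with SAP.  Clamp onsets add a
spike-then-dip transient to ``rho`` over the first ~20 s of clamping.

Every quantity a downstream stage estimates (per-beat SAP, rho, Pf, Pb,
tau, beat times; per-sample forward/riding/drift components) is returned as
:class:`GroundTruth`, so recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal import Signal

DEFAULT_PROTOCOL = (("clamp", 60.0), ("relax", 60.0), ("clamp", 60.0), ("relax", 60.0))
DEFAULT_SAP_LEVELS = {"clamp": 140.0, "relax": 100.0}


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters; defaults are the emulated experiment's values.

    Pressures in mmHg, rates in Hz, times in seconds.  ``rho_gain`` /
    ``tau_gain`` couple the reflection ratio and R-to-systolic delay
    linearly to the instantaneous SAP level (per mmHg above
    ``sap_reference``).
    """

    rate: float = 1000.0
    heart_rate: float = 3.1
    respiration_rate: float = 0.34
    protocol: tuple[tuple[str, float], ...] = DEFAULT_PROTOCOL
    sap_levels: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SAP_LEVELS)
    )
    sap_baseline: float = 100.0
    diastolic: float = 70.0
    resp_fraction: float = 0.05
    rho_baseline: float = 0.25
    rho_gain: float = 0.0025
    sap_reference: float = 100.0
    # dicrotic riding wave as prominent as the reflected one: keeps the
    # riding component narrowband at twice the cardiac rate, so its
    # amplitude is a well-defined estimand for wave separation
    dicrotic_fraction: float = 1.0
    tau_baseline: float = 0.12
    tau_gain: float = -0.00075
    clamp_transient: bool = True
    snr_db: float = 20.0
    drift_amplitude: float = 2.0
    drift_rate: float = 0.043
    seed: int = 0
    transition_scale: float = 2.3  # logistic time scale, 10-90% rise ~ 10 s

    def __post_init__(self) -> None:
        if self.rate <= 0 or self.heart_rate <= 0 or self.respiration_rate <= 0:
            raise ValueError("all rates must be positive")
        if not self.protocol or any(d <= 0 for _, d in self.protocol):
            raise ValueError("protocol phases need positive durations")
        if any(name not in self.sap_levels for name, _ in self.protocol):
            raise ValueError("every protocol phase needs a SAP level")
        if not (0.0 <= self.rho_baseline <= 0.5):
            raise ValueError("rho baseline must lie in [0, 0.5]")
        if not (0.0 < self.tau_baseline < 1.0 / self.heart_rate):
            raise ValueError("tau baseline must be shorter than one beat")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.protocol))

    @property
    def phase_starts(self) -> np.ndarray:
        return np.concatenate(([0.0], np.cumsum([d for _, d in self.protocol])[:-1]))


@dataclass(frozen=True)
class GroundTruth:
    """Everything the generator knows about its own output.

    ``beats`` has one row per beat: ``t_r`` (R time), ``t_sys`` (systolic
    time), ``t_onset``, ``sap``, ``pf``, ``pb``, ``rho``, ``tau``.
    Per-sample arrays share the output signals' grid.
    """

    beats: pd.DataFrame
    forward: np.ndarray
    riding: np.ndarray
    drift: np.ndarray
    bp_clean: np.ndarray
    ecg_clean: np.ndarray
    resp_factor: np.ndarray
    config: SimulationConfig


def _sap_trajectory(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Per-sample SAP target: logistic steps between phase levels."""
    levels = [config.sap_levels[name] for name, _ in config.protocol]
    out = np.full_like(t, config.sap_baseline, dtype=float)
    prev = config.sap_baseline
    for start, level in zip(config.phase_starts, levels):
        out += (level - prev) / (1.0 + np.exp(-(t - start) / config.transition_scale))
        prev = level
    return out


def _rho_transient(config: SimulationConfig, t: np.ndarray) -> np.ndarray:
    """Spike-then-dip excursion of rho after each clamp onset."""
    out = np.zeros_like(t)
    if not config.clamp_transient:
        return out
    for (name, _), start in zip(config.protocol, config.phase_starts):
        if name != "clamp":
            continue
        dt = t - start
        mask = dt >= 0
        out[mask] += 0.15 * np.exp(-dt[mask] / 3.0) - 0.08 * np.exp(-dt[mask] / 12.0)
    return out


def protocol_sap(config: SimulationConfig) -> np.ndarray:
    """Per-beat target SAP sequence implied by the protocol (no respiration)."""
    t_sys = _beat_times(config) + _tau_of(config, _beat_times(config))
    return _sap_trajectory(config, t_sys)


def _beat_times(config: SimulationConfig) -> np.ndarray:
    period = 1.0 / config.heart_rate
    start = 0.25
    n_beats = int(np.floor((config.duration - start - 0.35) / period)) + 1
    return start + period * np.arange(n_beats)


def _tau_of(config: SimulationConfig, t_r: np.ndarray) -> np.ndarray:
    sap = _sap_trajectory(config, t_r)
    tau = config.tau_baseline + config.tau_gain * (sap - config.sap_reference)
    return np.clip(tau, 0.03, 0.9 / config.heart_rate)


def _gauss_add(out: np.ndarray, t: np.ndarray, rate: float,
               center: float, amp: float, sigma: float) -> None:
    lo = max(0, int((center - 4 * sigma) * rate))
    hi = min(out.size, int((center + 4 * sigma) * rate) + 1)
    if hi <= lo:
        return
    seg_t = t[lo:hi]
    out[lo:hi] += amp * np.exp(-0.5 * ((seg_t - center) / sigma) ** 2)


def simulate(
    config: SimulationConfig | None = None,
) -> tuple[Signal, Signal, GroundTruth]:
    """Generate a synchronized (ECG, BP) pair with ground truth.

    Deterministic given ``config.seed``.  See the module docstring for the
    construction; the key identities are, per beat ``k``:

    * systolic peak time ``t_sys = t_R + tau_k``
    * forward pulse excursion ``Pf_k`` = SAP_k - diastolic, respiration-
      modulated
    * riding-wave systolic peak-to-trough ``Pb_k = rho_k/(1-rho_k) * Pf_k``
    """
    if config is None:
        config = SimulationConfig()
    rate = config.rate
    n = int(round(config.duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))

    t_r = _beat_times(config)
    tau = _tau_of(config, t_r)
    t_sys = t_r + tau
    sap_level = _sap_trajectory(config, t_sys)
    resp_beat = 1.0 + config.resp_fraction * np.sin(
        2 * np.pi * config.respiration_rate * t_sys
    )
    pf = (sap_level - config.diastolic) * resp_beat
    rho = np.clip(
        config.rho_baseline
        + config.rho_gain * (sap_level - config.sap_reference)
        + _rho_transient(config, t_sys),
        0.0,
        0.5,
    )
    pb = rho / (1.0 - rho) * pf

    beat_period = 1.0 / config.heart_rate
    # systolic upstroke ~42% of the beat: realistic at a fast pig heart rate
    # and keeps the forward pulse spectrally compact around the cardiac
    # fundamental, as the wave-separation model assumes
    t_up = 0.42 * beat_period
    onsets = t_sys - t_up

    forward = np.full(n, 0.0)
    k_on = np.round(onsets * rate).astype(int)
    k_sys = np.round(t_sys * rate).astype(int)
    k_end = np.append(k_on[1:], min(n, k_on[-1] + int(beat_period * rate)))
    for k in range(t_r.size):
        lo, mid, hi = k_on[k], k_sys[k], k_end[k]
        if hi > n or mid <= lo or hi <= mid:
            continue
        u = (np.arange(lo, mid) - lo) / (mid - lo)
        forward[lo:mid] = pf[k] * 0.5 * (1 - np.cos(np.pi * u))
        w = (np.arange(mid, hi) - mid) / (hi - mid)
        forward[mid:hi] = pf[k] * 0.5 * (1 + np.cos(np.pi * w))

    # Riding wave: amplitude-modulated carrier at twice the heart rate,
    # phase-locked so a crest sits on every systolic peak.  The envelope is
    # smooth and continuous across beats: a raised-cosine-squared lobe of
    # half-beat width boosts the systolic (reflected) crest above the
    # diastolic (dicrotic) level, and per-beat amplitudes are interpolated
    # between systolic instants.  By construction the systolic
    # peak-to-trough swing of the riding wave equals pb exactly.
    dic = config.dicrotic_fraction
    amp = np.interp(t, t_sys, pb / (1.0 + dic))
    nearest = np.clip(
        np.searchsorted(0.5 * (t_sys[:-1] + t_sys[1:]), t), 0, t_sys.size - 1
    )
    delta = t - t_sys[nearest]  # time since the nearest systolic peak
    carrier = np.cos(2 * np.pi * 2 * config.heart_rate * delta)
    lobe = np.where(
        np.abs(delta) <= beat_period / 4.0,
        np.cos(2 * np.pi * delta / beat_period) ** 2,
        0.0,
    )
    riding = amp * (dic + (1.0 - dic) * lobe) * carrier
    riding[: k_on[0]] = 0.0

    drift = config.drift_amplitude * np.sin(2 * np.pi * config.drift_rate * t + 0.7)
    bp_clean = config.diastolic + forward + riding
    ac = bp_clean - bp_clean.mean()
    bp_noise_std = float(np.sqrt(np.var(ac) / 10 ** (config.snr_db / 10)))
    bp_samples = bp_clean + drift + rng.normal(0.0, bp_noise_std, n)

    ecg_clean = np.zeros(n)
    for k in range(t_r.size):
        _gauss_add(ecg_clean, t, rate, t_r[k], 1.0, 0.012)       # R
        _gauss_add(ecg_clean, t, rate, t_r[k] - 0.13, 0.12, 0.022)  # P
        _gauss_add(ecg_clean, t, rate, t_r[k] + 0.16, 0.18, 0.032)  # T
    ecg_noise_std = float(
        np.sqrt(np.var(ecg_clean) / 10 ** (config.snr_db / 10))
    )
    ecg_samples = ecg_clean + rng.normal(0.0, ecg_noise_std, n)

    beats = pd.DataFrame(
        {
            "t_r": t_r,
            "t_sys": t_sys,
            "t_onset": onsets,
            "sap": config.diastolic + pf,
            "pf": pf,
            "pb": pb,
            "rho": rho,
            "tau": tau,
        }
    )
    resp_factor = 1.0 + config.resp_fraction * np.sin(
        2 * np.pi * config.respiration_rate * t
    )
    truth = GroundTruth(
        beats=beats,
        forward=forward,
        riding=riding,
        drift=drift,
        bp_clean=bp_clean,
        ecg_clean=ecg_clean,
        resp_factor=resp_factor,
        config=config,
    )
    return (
        Signal(ecg_samples, rate, "ecg"),
        Signal(bp_samples, rate, "bp"),
        truth,
    )
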