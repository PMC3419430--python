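"""Model/Results interface tying the full ECG-BP analysis together.

:class:`CardioEEMD` is constructed from a synchronized ECG/BP pair and
``fit()`` runs the whole pipeline in order: ensemble decomposition of each
channel, Monte-Carlo verification of noisy IMFs, merging of split IMFs,
noise-removed reconstruction, beat detection, forward/riding wave
separation and both reflection indexes, the ECG-BP cardiac phase shift and
pulse transit time, and the pairwise correlation report.  The returned
:class:`CardioEEMDResults` carries every intermediate product, a beat table
(one row per detected beat), the per-sample phase-shift series and a
``summary()`` string.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import reflection as refl
from . import phase as phs
from .correlation import correlation_table
from .eemd import EnsembleParams, eemd, merge_split_imfs
from .emd import IMFSet
from .significance import (
    MCVerification,
    WhiteNoiseReference,
    classify_imfs,
    denoise,
    white_noise_reference,
)
from .signal import Signal


@lru_cache(maxsize=4)
def default_reference(
    n_samples: int = 2048, n_realizations: int = 100, seed: int = 314159
) -> WhiteNoiseReference:
    """Process-wide cached white-noise band (the expensive Monte-Carlo step).

    The band is rate-free and applies to decompositions of any signal, so a
    single simulation serves every model fit; the fixed seed keeps results
    reproducible across runs.
    """
    return white_noise_reference(n_samples, n_realizations, seed=seed)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name and cause."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CardioEEMDResults:
    """Everything one fit produces.

    ``beats`` columns: ``onset, peak, t_onset, t_peak, sap, pf, pb,
    ri_eemd, ri_eemd_smooth, ejection_time, ri_referred,
    ri_referred_smooth, ptt, phase_shift`` — sample indices, seconds, mmHg
    and dimensionless indexes per beat.  The correlation table pairs the
    smoothed index series (the respiratory swing filtered out) with SAP.
    """

    model: "CardioEEMD"
    ecg_imfs: IMFSet
    bp_imfs: IMFSet
    bp_verification: MCVerification
    ecg_verification: MCVerification
    beats: pd.DataFrame
    phase: phs.PhaseShiftSeries
    correlations: pd.DataFrame
    heart_rate_hz: float
    riding_imf_index: int
    ecg_cardiac_index: int
    bp_cardiac_index: int
    denoised_bp: Signal
    forward: Signal
    riding: Signal
    params: dict

    def summary(self) -> str:
        b = self.beats
        lines = [
            "CardioEEMD analysis summary",
            "===========================",
            f"channels: ECG ({self.model.ecg.n} samples), "
            f"BP ({self.model.bp.n} samples) at {self.model.rate:g} Hz "
            f"({self.model.bp.duration:.1f} s)",
            f"ensemble size {self.params['ensemble_size']}, "
            f"noise ratio {self.params['noise_ratio']}, seed {self.params['seed']}",
            f"beats detected: {len(b)}   heart rate: {self.heart_rate_hz:.2f} Hz",
            f"riding-wave IMF (BP): {self.riding_imf_index + 1}   "
            f"cardiac IMFs: ECG {self.ecg_cardiac_index + 1}, "
            f"BP {self.bp_cardiac_index + 1}",
            f"BP IMF flags: {', '.join(self.bp_verification.flags)}",
            "",
            "per-beat medians",
            "----------------",
            f"SAP {b['sap'].median():8.2f} mmHg    Pf {b['pf'].median():6.2f} mmHg"
            f"    Pb {b['pb'].median():6.2f} mmHg",
            f"RI (EEMD) {b['ri_eemd'].median():6.3f}    "
            f"RI (referred) {b['ri_referred'].median():6.3f}    "
            f"PTT {b['ptt'].median() * 1000:6.1f} ms",
            f"ECG-BP cardiac phase shift {b['phase_shift'].median():6.3f} rad",
            "",
            "pairwise correlations (|r| descending)",
            "--------------------------------------",
        ]
        for _, row in self.correlations.iterrows():
            lines.append(
                f"{row.label_a:>12s} ~ {row.label_b:<12s} "
                f"r = {row.r:+.3f}  {row.sign} and {row.category}"
            )
        return "\n".join(lines)

    def save(self, outdir) -> None:
        """Write every product to ``outdir`` (CSV/JSON)."""
        from . import io as cio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        cio.write_imfset(self.ecg_imfs, outdir / "ecg_imfs.csv")
        cio.write_imfset(self.bp_imfs, outdir / "bp_imfs.csv")
        self.bp_verification.to_json(outdir / "bp_verification.json")
        self.ecg_verification.to_json(outdir / "ecg_verification.json")
        cio.write_table(self.beats, outdir / "beats.csv")
        cio.write_table(self.phase.to_frame(), outdir / "phase_shift.csv")
        cio.write_table(self.correlations, outdir / "correlations.csv")
        cio.write_json(
            self.correlations.to_dict(orient="records"), outdir / "correlations.json"
        )
        cio.write_json(
            {
                "params": self.params,
                "heart_rate_hz": self.heart_rate_hz,
                "riding_imf_index": self.riding_imf_index + 1,
                "ecg_cardiac_index": self.ecg_cardiac_index + 1,
                "bp_cardiac_index": self.bp_cardiac_index + 1,
                "n_beats": len(self.beats),
                "median_ri_eemd": float(self.beats["ri_eemd"].median()),
                "median_ri_referred": float(self.beats["ri_referred"].median()),
                "median_ptt_s": float(self.beats["ptt"].median()),
            },
            outdir / "run_summary.json",
        )
        (outdir / "summary.txt").write_text(self.summary() + "\n")

    def plot(self, show: bool = False):
        """Diagnostic figure: BP with beats, RI series, phase shift."""
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(3, 1, figsize=(10, 8), sharex=True)
        bp = self.model.bp
        axes[0].plot(bp.time, bp.samples, lw=0.4, label="BP")
        axes[0].plot(
            self.beats["t_peak"], self.beats["sap"], "r.", ms=3, label="SAP"
        )
        axes[0].set_ylabel("BP [mmHg]")
        axes[0].legend(loc="upper right")
        axes[1].plot(self.beats["t_peak"], self.beats["ri_eemd"], ".", ms=3,
                     label="RI (EEMD)")
        axes[1].plot(self.beats["t_peak"], self.beats["ri_eemd_smooth"], "-",
                     label="RI smoothed")
        axes[1].plot(self.beats["t_peak"], self.beats["ri_referred"], ".", ms=3,
                     alpha=0.5, label="RI referred")
        axes[1].set_ylabel("RI")
        axes[1].legend(loc="upper right")
        axes[2].plot(self.phase.time, self.phase.shift_smoothed, lw=0.6)
        axes[2].set_ylabel("phase shift [rad]")
        axes[2].set_xlabel("time [s]")
        fig.tight_layout()
        if show:  # pragma: no cover - interactive use
            plt.show()
        return fig


class CardioEEMD:
    """EEMD-based cardiovascular analysis of a synchronized ECG/BP pair.

    Parameters
    ----------
    ecg, bp : Signal
        Synchronized channels sampled at the same rate.
    ensemble_size, noise_ratio : int, float
        Ensemble decomposition parameters (defaults 100 and 0.2).
    ri_window : int
        Moving-average window (in beats) for the reflection-index series;
        default 9, about one respiratory cycle of beats.
    shift_window : int or None
        Moving-average window (in samples) for the phase-shift series;
        default ``None`` picks the ~10 Hz equivalent cutoff,
        ``round(rate / 10)`` (100 samples at 1000 Hz).
    min_rate, max_rate : float
        Admissible heart-rate band in Hz for beat detection.
    """

    def __init__(
        self,
        ecg: Signal,
        bp: Signal,
        *,
        ensemble_size: int = 100,
        noise_ratio: float = 0.2,
        max_imfs: int = 12,
        ri_window: int = refl.DEFAULT_RI_WINDOW,
        shift_window: int | None = None,
        min_rate: float = 1.0,
        max_rate: float = 5.0,
        reference: WhiteNoiseReference | None = None,
    ):
        if ecg.rate != bp.rate:
            raise ValueError("ECG and BP must share a sampling rate")
        if ecg.n != bp.n:
            raise ValueError("ECG and BP must be synchronized (equal length)")
        self.ecg = ecg
        self.bp = bp
        self.rate = ecg.rate
        self.ensemble_size = ensemble_size
        self.noise_ratio = noise_ratio
        self.max_imfs = max_imfs
        self.ri_window = ri_window
        self.shift_window = (
            int(round(self.rate / 10.0)) if shift_window is None else shift_window
        )
        self.min_rate = min_rate
        self.max_rate = max_rate
        self.reference = reference

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        ecg_col: str = "ecg",
        bp_col: str = "bp",
        time_col: str | None = None,
        rate: float | None = None,
        **kwargs,
    ) -> "CardioEEMD":
        """Build the model from a DataFrame with ECG and BP columns.

        The rate comes from ``rate`` or from the spacing of ``time_col``.
        """
        if rate is None:
            if time_col is None:
                raise ValueError("provide rate or a time column")
            steps = np.diff(frame[time_col].to_numpy(dtype=float))
            if steps.size == 0 or np.any(steps <= 0):
                raise ValueError("time column must be strictly increasing")
            rate = 1.0 / float(np.median(steps))
        ecg = Signal(frame[ecg_col].to_numpy(dtype=float), rate, ecg_col)
        bp = Signal(frame[bp_col].to_numpy(dtype=float), rate, bp_col)
        return cls(ecg, bp, **kwargs)

    def fit(self, seed: int = 0) -> CardioEEMDResults:
        """Run the full analysis; deterministic given ``seed``."""
        ref = self.reference if self.reference is not None else default_reference()
        seeds = [
            int(s.generate_state(1)[0] % (2**31))
            for s in np.random.SeedSequence(seed).spawn(2)
        ]

        def stage(name, fn, *args, **kw):
            try:
                return fn(*args, **kw)
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        ens = lambda s: EnsembleParams(
            ensemble_size=self.ensemble_size,
            noise_ratio=self.noise_ratio,
            seed=s,
            max_imfs=self.max_imfs,
        )
        bp_dec = stage("eemd-bp", eemd, self.bp, ens(seeds[0]))
        ecg_dec = stage("eemd-ecg", eemd, self.ecg, ens(seeds[1]))

        bp_merged = stage("merge-bp", merge_split_imfs, bp_dec)
        ecg_merged = stage("merge-ecg", merge_split_imfs, ecg_dec)
        bp_ver = stage("verify-bp", classify_imfs, bp_merged, ref)
        ecg_ver = stage("verify-ecg", classify_imfs, ecg_merged, ref)

        den_bp = stage("denoise-bp", denoise, bp_merged, bp_ver, True)
        bp_baseline = stage("denoise-bp-trend", denoise, bp_merged, bp_ver, False)

        beats = stage(
            "detect-beats", refl.detect_beats, den_bp, self.min_rate, self.max_rate
        )
        if len(beats) < 3:
            raise PipelineError("detect-beats", ValueError("fewer than 3 beats"))
        # SAP from the trend-preserving reconstruction: physiological
        # baseline retained, high-frequency noise removed
        beats["sap"] = bp_baseline.samples[beats["peak"].to_numpy()]
        ibi = np.diff(beats["t_peak"].to_numpy())
        heart_rate = 1.0 / float(np.median(ibi))

        forward, riding, riding_idx = stage(
            "separate-waves", refl.separate_waves, bp_merged, bp_ver, heart_rate
        )
        beats = stage("beat-amplitudes", refl.beat_amplitudes, forward, riding, beats)
        w = min(self.ri_window, len(beats) if len(beats) % 2 else len(beats) - 1)
        beats["ri_eemd_smooth"] = refl.moving_average(
            np.nan_to_num(beats["ri_eemd"].to_numpy(),
                          nan=float(beats["ri_eemd"].median())),
            max(w, 1),
        )
        beats = stage(
            "referred-ri", refl.referred_ri, bp_baseline, beats, riding
        )
        w_ref = min(self.ri_window, len(beats) if len(beats) % 2 else len(beats) - 1)
        beats["ri_referred_smooth"] = refl.moving_average(
            np.nan_to_num(beats["ri_referred"].to_numpy(),
                          nan=float(beats["ri_referred"].median())),
            max(w_ref, 1),
        )

        ecg_cardiac_idx = stage(
            "select-cardiac-ecg", phs.select_cardiac_imf, ecg_merged, heart_rate
        )
        bp_cardiac_idx = stage(
            "select-cardiac-bp", phs.select_cardiac_imf, bp_merged, heart_rate
        )
        shift = stage(
            "phase-shift",
            phs.phase_shift,
            ecg_merged.imfs[ecg_cardiac_idx],
            bp_merged.imfs[bp_cardiac_idx],
            self.rate,
            self.shift_window,
        )
        beats = stage(
            "ptt",
            phs.pulse_transit_time,
            ecg_merged.imf_signal(ecg_cardiac_idx, "ecg-cardiac"),
            beats,
            heart_rate,
            self.ecg,
        )
        # per-beat mean of the smoothed shift for beat-aligned correlation
        bounds = np.append(beats["onset"].to_numpy(), self.bp.n)
        shift_beat = np.array(
            [
                float(np.mean(shift.shift_smoothed[lo:hi])) if hi > lo else np.nan
                for lo, hi in zip(bounds[:-1], bounds[1:])
            ]
        )
        beats["phase_shift"] = shift_beat

        # correlate the respiration-filtered index series: the raw per-beat
        # RI carries the cyclic respiratory swing that the moving-average
        # filter exists to remove
        corr = stage(
            "report",
            correlation_table,
            {
                "sap": beats["sap"].to_numpy(),
                "ri_eemd": beats["ri_eemd_smooth"].to_numpy(),
                "ri_referred": beats["ri_referred_smooth"].to_numpy(),
                "phase_shift": beats["phase_shift"].to_numpy(),
            },
        )
        params = {
            "ensemble_size": self.ensemble_size,
            "noise_ratio": self.noise_ratio,
            "max_imfs": self.max_imfs,
            "ri_window": self.ri_window,
            "shift_window": self.shift_window,
            "min_rate": self.min_rate,
            "max_rate": self.max_rate,
            "seed": seed,
            "channel_seeds": seeds,
            "rate_hz": self.rate,
        }
        return CardioEEMDResults(
            model=self,
            ecg_imfs=ecg_merged,
            bp_imfs=bp_merged,
            bp_verification=bp_ver,
            ecg_verification=ecg_ver,
            beats=beats,
            phase=shift,
            correlations=corr,
            heart_rate_hz=heart_rate,
            riding_imf_index=riding_idx,
            ecg_cardiac_index=ecg_cardiac_idx,
            bp_cardiac_index=bp_cardiac_idx,
            denoised_bp=den_bp,
            forward=forward,
            riding=riding,
            params=params,
        )
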