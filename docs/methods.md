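# Methods

`cardioemd` analyses synchronized ECG and arterial blood-pressure (BP)
recordings with ensemble empirical mode decomposition (EEMD) and derives two
beat-resolved cardiovascular indexes: a wave reflection index (an arterial
stiffness indicator) and the ECG–BP cardiac-oscillation phase shift (a
systemic impedance indicator).  This note documents the model, the numerical
conventions, the synthetic data generator, and the design choices made where
the underlying procedure is open to interpretation.

## Empirical mode decomposition

EMD extracts intrinsic mode functions (IMFs) by sifting: the mean of the
cubic-spline envelopes through the local maxima and minima is repeatedly
subtracted until it is close to zero, the resulting oscillation is removed
from the signal, and the procedure repeats on the remainder.  The
decomposition is complete by construction — the IMFs plus the final residue
sum to the input to round-off — and IMFs appear in order of decreasing
characteristic frequency.

Conventions where the classical recipe leaves freedom:

* **Stopping rule.**  Sifting stops when the Cauchy criterion
  `SD = Σ(h_prev − h_new)² / Σ h_prev² < 0.2`, with a floor of 10 and a cap
  of 50 iterations.  The floor is load-bearing: with the SD test alone,
  sifting on broadband signals stops after 2–3 iterations and the resulting
  dyadic filter bank spaces its bands ≈ 2.4× apart in frequency.  Such a
  bank cannot hold apart two oscillations one octave apart — precisely the
  relationship between the cardiac mode at the heart rate f₀ and the riding
  (reflected + dicrotic) wave at 2·f₀ that the reflection index depends on.
  Ten siftings restore the classic factor-2 bank (verified on white noise:
  per-IMF mean-frequency ratios 1.95–2.1).
* **Boundaries.**  The two extrema nearest each end are mirrored across the
  end sample before spline fitting, limiting end swings that would corrupt
  beat-level amplitudes.
* **Plateaus.**  A run of equal samples contributes one extremum at its
  midpoint (deterministic tie-break).
* **Maximum IMF count** defaults to 12, enough for the ~9 modes seen in
  minutes-long recordings at 250–1000 Hz with margin.

## Ensemble EMD

Mode mixing — intermittent activity splitting one physical oscillation
across IMFs or fusing different scales into one — is repaired by averaging
the decompositions of `signal + ε_k` over many independent white-noise
realizations `ε_k` (default 100 members, noise std 0.2 × signal std).  Each
member draws its noise from a stream spawned from the master seed, so
results are bit-reproducible.  Members can produce different IMF counts;
short members are padded with zero IMFs before the component-wise average,
preserving the ensemble-mean semantics.  The added noise cancels as
1/ensemble-size in the reconstruction; the intrinsic measurement noise of
the recording is unaffected (it is coherent across members) and is handled
by the Monte-Carlo verification below.

An intrinsic component can still emerge split across two adjacent ensemble
IMFs.  `merge_split_imfs` re-joins an adjacent pair when the two are both
strongly correlated (|Pearson r| ≥ 0.5) **and** of similar averaged
frequency (ratio within 1.25).  Both conditions are required: the riding
wave at 2·f₀ is phase-locked to the cardiac mode and typically correlates
with it at |r| ≈ 0.5, but merging them would destroy the wave separation;
the frequency condition is what distinguishes "one component split in two"
from "two components that co-vary".

Averaged IMF frequency is available in two conventions: zero-crossing count
over twice the duration (robust to amplitude modulation) and the
power-weighted spectral centroid (robust to spurious crossings in quiet
stretches).  Wave separation uses the centroid; cardiac-IMF selection for
the phase analysis uses zero crossings.

## Monte-Carlo verification of noisy IMFs

For unit-variance white noise, the per-IMF points (ln averaged period T̄ₙ,
ln energy density Eₙ) fall on a straight line of slope ≈ −1.  The package
simulates this line empirically: 100 white-noise sequences (4096 samples in
the acceptance configuration, 2048 in the cached pipeline default) are
decomposed by plain EMD, the pooled points are fitted by least squares, and
the band is the 1st–99th percentile of the fit residuals.  Eₙ is the mean
squared sample; T̄ₙ is the reciprocal of the spectral-centroid frequency —
the discrete form of the spectrum-weighted mean period.

Classifying a real decomposition requires matching the band to the
recording's own noise level.  The first IMF of a noisy recording is taken
as (almost) pure noise: the band is shifted vertically by
`ln E₁(observed) − mean ln E₁(reference)`.  This anchoring is what lets a
clean oscillation be recognized: its first IMF sits at a much longer period
than a first-order noise IMF, so after anchoring its point lies far above
the band and it is flagged signal.  The leading contiguous run of IMFs
inside the shifted band is flagged noise (only the leading run — noise in
this model occupies the first n IMFs); IMFs with averaged period longer
than a quarter of the record are trend-like (too few cycles to judge, which
also covers slow drifts and, e.g., sub-cardiac components of unclear
origin); everything else is signal.  The noise-removed waveform is the sum
of signal IMFs, optionally plus trend IMFs and residue when the baseline is
wanted.

## Reflection index

The arterial pulse is modelled as a forward (ejection-driven) wave plus a
riding component at twice the cardiac rate that carries the reflected wave
(cresting with the systolic peak) and the dicrotic wave (after valve
closure).  After verification and merging, the riding component is the
signal-flagged IMF whose centroid frequency is nearest 2·f₀ (within ±50%);
the forward wave is the sum of the remaining signal IMFs, so forward +
riding equals the noise-removed reconstruction exactly.  The IMF nearest f₀
(the cardiac mode itself) is never eligible as the riding wave; without
this exclusion a weak-reflection recording, where no 2·f₀ mode forms, would
select the cardiac IMF (its frequency can sit just inside the ±50% band)
and report a nonsensical RI near 1.

Per beat (onset-to-onset, onsets at the diastolic minima preceding
prominence-detected systolic peaks at an admissible 1–5 Hz rate):

* `Pf` = max − min of the forward wave in the beat;
* `Pb` = peak-to-trough swing of the riding oscillation whose crest
  accompanies the systolic peak (nearest riding peak within a quarter beat;
  measured down to the following trough).  The second, dicrotic riding
  crest is excluded.  Beats without a systolic-coincident riding crest get
  `Pb = NaN` and drop out of correlations.  "Amplitude" of the riding wave
  is read as the full swing; the recovery tolerances absorb the convention.
* `RI = Pb / (Pb + Pf)` ∈ [0, 1).

The reference ("referred") algorithm approximates the aortic flow pulse as
a triangle of duration equal to the ejection time, which places the
pressure inflection at 30% of the ejection time after the beat onset:
`Pf = BP(inflection) − BP(onset)`, `Pb = SAP − BP(inflection)` (floored at
zero), same RI formula.  Ejection time is estimated as onset-to-dicrotic
notch, the notch being the riding component's minimum after the systolic
peak; when no riding component is available the fallback is time-to-peak
plus 0.1 s.  A per-beat ejection-time override exists for validation
against constructed waveforms.  The referred RI is evaluated on the
noise-removed (trend-preserving) reconstruction: it reads single samples at
the onset and inflection, which on the raw signal are dominated by
measurement noise.

Per-beat RI series are smoothed with a centered 9-beat moving average
(truncated at the edges) before cross-index correlation: at a ~3 Hz heart
rate and ~0.34 Hz respiration, 9 beats is one respiratory cycle, and the
filter removes exactly the cyclic respiratory swing visible in per-beat
SAP.  The respiratory period itself is measured by `cyclic_period`:
detrend by the same moving average, count ascending zero crossings, divide
the time span between first and last crossing by the number of full cycles.

## Phase shift and pulse transit time

The ECG is treated as the driving signal and BP as the output of the
cardiovascular system, so systemic impedance appears as a phase delay
between their *cardiac oscillations* — the IMF of each channel whose
zero-crossing frequency is nearest the heart rate (accepted within a ratio
band [0.6, 1.67]).  The Hilbert transform gives each cardiac IMF's
instantaneous phase; unwrapping yields the accumulative phase; the
per-sample difference `phase_ecg − phase_bp` is the phase shift (positive =
BP lags ECG; a pure delay τ at carrier f maps to 2πfτ).  The shift is
smoothed with a centered moving average of ~rate/10 samples (100 at
1000 Hz, an equivalent ~10 Hz cutoff); an even requested window is rounded
up to the next odd length, since the smoother is strictly centered.

Pulse transit time (PTT) is the delay from each R peak to the next systolic
peak.  R peaks are detected on the ECG cardiac-band IMF by prominence and,
when the raw ECG is available, snapped to the raw maximum within ±40 ms:
the P and T waves contribute to the cardiac-band component and would
otherwise bias its crests away from the R instants by tens of
milliseconds.  Beats with no preceding R peak, or a non-positive delay, are
skipped.  On shared-carrier fixtures, phase shift / 2π ≈ PTT / beat
interval, and both are checked against injected delays.

## Correlation report

Pearson's product-moment coefficient with pairwise removal of undefined
beats; strength is banded by |r| at 0.20 / 0.40 / 0.60 / 0.80 into
negligible / low / moderate / significant / high ("significant" is a
magnitude band here, not a hypothesis test), boundaries assigned upward,
sign reported separately.  The beat-aligned table pairs SAP with the
smoothed RI series and the per-beat mean of the smoothed phase shift — the
unsmoothed series carry the respiratory cycling that the moving-average
filters exist to remove.

## Synthetic data generator

The generator emulates the recording situation the toolkit targets: an
anesthetized young pig whose intestinal artery is alternately clamped and
relaxed.  Defaults are the study conditions: 1000 Hz sampling, 3.1 Hz heart
rate, 0.34 Hz respiratory modulation, a clamp–relax–clamp–relax protocol of
four 60 s phases, systolic levels 140 mmHg (clamp) / 100 mmHg (relax) over
a 70 mmHg diastolic baseline, 20 dB measurement-noise SNR, a 2 mmHg
baseline drift at 0.043 Hz.  Protocol transitions are logistic with a ~10 s
10–90% rise.  Physiological couplings are linear with configurable gains —
reflection ratio ρ increases with SAP (+0.0025 /mmHg from 0.25 at
100 mmHg), R-to-systolic delay τ decreases with SAP (−0.75 ms/mmHg from
120 ms) — so the expected correlation pattern is known by construction, and
clamp onsets add a spike-then-dip transient to ρ over the first ~20 s.

Waveform choices, made for recoverability of the injected parameters
rather than morphological fidelity:

* The forward pulse is an asymmetric raised cosine with the upstroke
  occupying 42% of the beat — realistic at a fast pig heart rate, and
  spectrally compact: a sharper upstroke places substantial forward-wave
  harmonic energy at 2·f₀, where no frequency-based separation could
  distinguish it from the riding wave, making the injected `Pb`
  ill-defined as an estimand.
* The riding wave is an amplitude-modulated 2·f₀ carrier phase-locked to
  the systolic peaks, with a smooth, beat-continuous envelope; its systolic
  peak-to-trough swing equals `Pb = ρ/(1−ρ)·Pf` exactly.  The dicrotic
  fraction defaults to 1.0 (dicrotic crest as prominent as the reflected
  one): a weaker dicrotic level modulates the carrier *within* the beat,
  i.e. at f₀, moving 30–40% of the nominal riding amplitude to the cardiac
  frequency itself — energy that EMD then correctly assigns to the cardiac
  IMF and that no separation method could return to `Pb`.
* The ECG is a train of Gaussian bumps (R: 1.0 × 12 ms; P: 0.12 × 22 ms at
  −130 ms; T: 0.18 × 32 ms at +160 ms) with the systolic BP peak trailing
  each R peak by τ.

Ground truth (per-beat SAP, ρ, Pf, Pb, τ, beat times; per-sample forward,
riding, drift components) is returned alongside the signals.  What the
generator does **not** emulate: heart-rate variability and ectopy, Windkessel
or transmission-line hemodynamics, waveform-shape change with pressure,
movement artefacts, and amplitude-dependent (multiplicative) noise.  Tests
passing on this generator therefore demonstrate that the estimators recover
their estimands under stationary rhythm and additive noise, not that they
are robust to every feature of real recordings.

## Scales used by the automated checks

The test suite and the acceptance script scale runs to keep a full pass
fast while preserving the study conditions: reflection-ratio recovery uses
60 s single-phase runs at the native 1000 Hz with ensemble size 100; the
full-protocol correlation check uses the complete 240 s protocol at
500 Hz; the white-noise reference uses 4096 samples × 100 realizations
(the cached pipeline default is 2048 × 100); delay recovery uses 20 s
shared-carrier fixtures at 1000 Hz.

## Known limitations

* **Weak reflection is invisible to the decomposition.**  A riding wave
  needs either enough amplitude to create its own extrema against the
  forward upstroke slope or enough noise assistance to be expressed;
  below ρ ≈ 0.15–0.2 (riding swing ≲ 2 mmHg on a 30 mmHg pulse at 20 dB
  SNR, ensemble noise 0.2 × std) no 2·f₀ mode forms and `separate_waves`
  raises `SeparationError` rather than reporting a fabricated index.  This
  is a floor of the decomposition approach, not of the implementation.
* Recovered RI is mildly biased low (≈ −0.06 at ρ = 0.3) because the
  riding IMF's troughs, which fall on the forward wave's steep segments,
  are partially absorbed by the cardiac IMF; the systolic crest is
  recovered faithfully.  Correlation-based conclusions are unaffected.
* The dyadic filter bank makes results mildly sampling-rate dependent;
  analyses should run at the recording's native rate rather than on
  aggressively downsampled data (at 250 Hz the riding/cardiac octave falls
  too close to the discretization limit for reliable separation).
* The triangular (referred) RI assumes an inflection at 30% of ejection
  time, validated for central aortic pressure; on other sites it serves as
  a comparison index, not ground truth.
* The phase-shift sign convention (positive = BP lags ECG) is this
  package's choice; only relative changes and correlation signs are
  comparable across conventions.
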