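# Methods

This note documents the models, parameter choices, numerical decisions and
known limitations of `pulselock`, in the order the pipeline runs.

## Audio front end (`audiofeat`)

**Middle-ear filter.** A 4th-order Butterworth band-pass (two second-order
sections) emphasising ~0.5–5 kHz, the band the middle ear transmits best.
Exact middle-ear transfer functions vary across the literature; the filter
here is a plain LTI stand-in whose passband is the consensus region, and
it is applied causally so the impulse response is exactly the designed
one.  When the sample rate is only 8 kHz the upper edge is pulled to
0.45·fs to stay below Nyquist.  Input below 8 kHz is rejected.

**Complex-domain onset detection.** STFT with a 46 ms Hann window and
11.6 ms hop (~86 frames/s — ample for rhythm content below 8 Hz).  Per
frame the predicted spectrum carries the previous frame's magnitude with
phase linearly extrapolated from the two previous frames; onset strength
is the summed complex deviation from that prediction.  The first two
frames are defined as zero.  The raw function responds to any spectral
change (including note releases); before driving the oscillator bank it
is median-detrended over ~1 s and half-wave rectified, which stabilises
the forcing baseline across recordings of different density and loudness.
Detected event times carry an inherent ~1-frame latency (the frame in
which the deviation is observed) and a ±half-window smear.

**Amplitude envelope.** Magnitude of the analytic signal of the
middle-ear-filtered waveform, low-passed at 50 Hz (4th-order zero-phase
Butterworth), polyphase-resampled to the analysis rate, clipped at zero.
`method="rectify"` substitutes full-wave rectification for the analytic
magnitude; both are common dialects and the choice is recorded in the run
configuration.  The envelope is linear in the input scale
(envelope(c·x) = c·envelope(x)), which the tests enforce.

## Oscillator network (`grfnn`)

Each of 76 oscillators (15 bins/octave over 0.25–8 Hz, matching the
wavelet density so pulse estimates align with PLV bins) integrates

    dz/dt = f · [ z(α + i2π + β₁|z|² + εβ₂|z|⁴/(1−ε|z|²)) + c·s(t) ]

with the onset signal s(t) as common forcing.  Defaults put the bank at
criticality: α = 0, β₁ = β₂ = −1, ε = 0.5, c = 1.  In this regime the
origin is marginally stable, response to periodic forcing is sharply
frequency-selective, and amplitudes saturate well below the singularity
at |z|² = 1/ε; ε|z|² ≥ 1 raises an explicit blow-up error naming the
oscillator and time.  Parameters were chosen so that click-train fixtures
produce amplitude peaks at the pulse and its 1:2 / 2:1 / 3:1 partners,
and they are fully config-exposed.  Integration is fixed-step RK4 at
250 Hz (the onset signal is linearly interpolated onto the half-step
grid and scaled so its 95th percentile is 1); amplitudes are stored at
25 Hz, ample for salience windows of seconds.

**Metrical-frequency rule.** Salience is the *mean* amplitude over the
analysis window (mean rather than peak: robust to the amplitude ripple a
click train induces).  The pulse is chosen among local maxima of the
salience profile at ≤ 3.5 Hz (the delta/theta boundary, inclusive) that
exceed the median salience by 50% — a flat, noise-driven profile
therefore yields an explicit "no pulse" failure rather than an arbitrary
argmax.  Near-ties break toward the *lower* frequency: any admissible
peak within 15% (relative salience) of the best one wins if slower.  This
matters for slow tempi, where a harmonic of the beat resonates about as
strongly as the beat itself (for a 0.8 Hz click train the 2.4 Hz partner
is marginally stronger), and encodes the preference for the slower pulse
percept.  The harmonic is the most salient frequency ≥ 3.5 Hz within 6%
of 2×, 3× or 4× the pulse; the subharmonic the most salient within 6% of
pulse/2 or pulse/3; either may be absent.  An oscillator at exactly
3.5 Hz may serve as pulse or harmonic but not both in one estimate
(pulse takes precedence).

**Stable epoch.** The three frequencies are tracked in 10 s windows with
a 1 s hop; the detector returns the earliest interval of ≥ 120 s in which
each tracked series stays within ±5% of its interval median (pulse must
be defined throughout; subharmonic/harmonic are checked where present).
The 5% tolerance is deliberate: the frequency grid spacing is
2^(1/15) − 1 ≈ 4.7%, so a perfectly stable off-grid tempo flaps between
adjacent bins by more than 4% and a tighter tolerance would reject
everything.  Epoch boundaries are quantized to the 1 s hop, so an epoch
can begin up to one hop before a tempo step whose window content is
already dominated by the post-step tempo.  Recordings without a stable
epoch (including all recordings shorter than 2 minutes) are excluded,
with machine-readable reasons in the run report.

## EEG preprocessing (`eegprep`)

Deterministic stages only: epoching to [first start − 1 s, last end + 1 s];
polyphase anti-aliased downsampling; re-referencing to the mean of
TP9/TP10 (which are then dropped); a zero-phase windowed-sinc FIR
band-pass 1–55 Hz (Hamming window, transition width 25% of the 1 Hz
cutoff, odd length applied centred so the phase response is exactly zero)
plus a zero-phase IIR notch at 60 Hz (Q = 30, adequate for stationary
line noise); and joint-probability bad-channel flagging — each channel's
mean negative log-probability under the pooled amplitude histogram,
normalized to leave-one-out z-scores, flagged above z = 5.  Artifact
subspace reconstruction, ICA and channel interpolation are intentionally
out of scope: they target biological artifacts the synthetic data does
not contain, and externally cleaned real recordings can enter at this
stage's output contract.  The whole chain is deterministic and preserves
a perfectly locked component: on synthetic EEG with κ = 1 and no noise,
PLV at the pulse after preprocessing stays ≥ 0.99 (tested).

## Entrainment statistic (`entrain`)

**Wavelet bank.** fₖ = 0.25·2^(k/15) Hz for k = 0…64 — 65 wavelets from
0.25 to 4.81 Hz.  Cycle counts follow clamp(round(2f), 3, 8): the plain
doubling rule alone would give 1–10 cycles over this range, so the clamp
is what realises the intended 3–8-cycle design; this reconciliation is a
deliberate dialect of the method.  Kernels are Gaussian-enveloped complex
exponentials with σ_t = cycles/(2πf), truncated at ±4σ_t and zero-mean
corrected, so a constant input transforms to exactly zero and is flagged
as phase-undefined rather than silently returned.

**PLV.** The magnitude of the mean resultant of e^{i(θ⁽¹⁾−θ⁽²⁾)}, so
0 ≤ PLV ≤ 1 by construction.  Samples within one wavelet half-support of
either signal edge are excluded per wavelet, and n counts only the
samples valid on both sides.  Convolution runs in the frequency domain
for signals longer than 8× the kernel and directly otherwise; both paths
agree to ~1e−10 (tested).  For i.i.d. uniform relative phases the
statistic's chance floor is √π/(2√n); note that wavelet-filtered noise is
strongly autocorrelated, so the *effective* n of real spectra is far
smaller than the sample count and empirical nulls sit well above the
i.i.d. formula — comparisons against chance in the tests use matched
empirical nulls.

**Pulse normalization.** u = 2f/pulse.  A pure bin shift would require
15·log₂(2/pulse) to be an integer, which generally fails (pulse 2.5 Hz →
4.83 bins), so each channel's PLV-vs-log₂f curve is linearly interpolated
onto a fixed dimensionless grid (15 bins/octave over [0.5, 8]).  Points
mapping outside the measured band are NaN, never extrapolated; points
within one bin of the band edge are flagged near-edge.  Level values at
u ∈ {1, 1.5, 2, 3, 4, 5} are read off by interpolation on that grid.
Consequence of the 4.81 Hz wavelet ceiling: recordings with pulse above
~2.4 Hz have no harmonic level (u = 4), and above ~1.9 Hz no off-harmonic
level (u = 5); aggregation simply averages the cells that exist.  PLV is
computed in a single window over the whole stable epoch (one sum over t),
not averaged over sub-windows.

## Statistics (`stats`)

Aggregation: unweighted mean over the recording × channel cross per
participant and level (order-invariant), and per-cluster means over the
nine 6-electrode clusters; the mastoid pair belongs to no cluster.
Bootstrap CIs are bias-adjusted normal-approximation intervals
((2θ̂ − θ̄*) ± z·sd*, 10,000 resamples), resampling participants — the
unit over which the grand average is defined.  The KS test and Holm
step-down correction follow their textbook definitions (Holm is
implemented directly and cross-checked against statsmodels).

Mixed-effects contrasts are delegated to statsmodels `MixedLM` (REML).
The grand-average design fits PLV ~ level × group with a participant
random intercept; the topographic design adds cluster and uses variance
components for uncorrelated cluster and level random slopes.  The
response is standardized before fitting (Wald/F statistics are invariant
to affine response scaling; unstandardized PLVs have variances ~1e−4
that destabilise the optimizer).  Each term is tested with a Wald F;
denominator degrees of freedom are n_participants − 2 for the
grand-average design (which reproduces lmerTest's Satterthwaite df and F
values on the same data — verified in a test against R's lme4/lmerTest)
and the residual count for the cluster design, where the two are
indistinguishable at thousands of observations.  If the mixed fit fails
to converge, the two-level design falls back to a documented
paired-contrast approximation: a one-sample t on per-participant level
differences (level), a two-sample t on participant means (group), and a
two-sample t on the differences (interaction).  Holm correction is
applied across the effect family of each model.  α = 0.05 throughout.

## Synthetic data (`synthgen`)

The generator emulates the features the analysis consumes, with defaults
chosen as the study conditions it stands in for:

- **Music**: percussive events as 5 ms raised-cosine noise bursts
  (broadband attacks → robust onset detection), inter-onset interval
  1/tempo(t), accents (amplitude 1.0 vs 0.6) every `meter` beats,
  optional tempo steps, optional white noise floor.  Ground-truth onset
  times are sample-exact.
- **EEG**: channel = Σ_level κ(ch, level)·cos(φ_level(t) + jitter) + 1/f
  noise, where φ_level is the instantaneous (narrowband Hilbert) phase of
  the envelope at the level frequency, jitter is a slow (< 0.5 Hz)
  Gaussian phase-noise process with configurable s.d., and the background
  is spectrally shaped 1/f noise (exponent 1).  The default channel set is
  the 54 clustered electrodes plus TP9/TP10.
- **Cohorts**: two groups of 16 participants × 6 recordings by default;
  pulse frequencies drawn log-normally with mode 2 Hz (σ = 0.3,
  truncated to [0.5, 4] by redraw) — a unimodal distribution of natural
  music tempi; participant-level coupling heterogeneity as a log-normal
  multiplier (cv = 0.2), which is what gives the random intercept real
  variance; a group effect as a multiplicative κ ratio OA/YA; optional
  (group, cluster, level) κ modifiers; an optional fraction of 90 s
  recordings that fail the 2-minute rule, emulating attrition.  Audio is
  written as 16-bit WAV, EEG as a BrainVision-style header/marker/binary
  triplet (a delimited channels × time format is also supported), and all
  ground truth goes into `manifest.json`.

**Scaled simulations.** Replicate-heavy validation (parameter-recovery
and type-I studies of the statistics) uses `gen_cohort_levels`, a
reduction that keeps the estimator and statistics chain but replaces the
audio/wavelet path with each cell's narrowband physics: the relative
phase between envelope and EEG is angle(κ·e^{i·jitter} + σ·ε) with ε
complex standard Gaussian, and the PLV of that series is computed with
the same `compute_plv` used on real data.  Problem sizes used by the
test suite: cohorts of 8+8 participants × 6 recordings, 500 relative-phase
samples per cell (300 under the null), 20 recovery replicates and 200
null replicates; the full audio → oscillator → wavelet chain is
exercised separately on single recordings and small cohorts.  What the
reduced path does *not* probe: wavelet leakage between neighbouring
levels, envelope-estimation error, and preprocessing interactions — those
are covered by the dedicated full-chain tests.

**What passing tests do not show about real data.** The generator's music
has flat broadband attacks and stationary 1/f EEG noise; real recordings
have sustained tonal content, expressive timing, and biological artifacts
(eye, muscle) that this pipeline deliberately leaves to upstream
cleaning.  Recovery rates measured here are therefore upper bounds on
real-data performance.

## Known limitations

- Pulse estimates are quantized to the 15-bins/octave grid (±2.3%); all
  recovery guarantees are "within one grid step".
- The Satterthwaite approximation is exact only for the balanced
  two-level design; cluster-model denominator df are residual-based.
- The harmonic/off-harmonic levels are structurally missing for fast
  pulses (wavelet ceiling at 4.81 Hz).
- The notch replaces multi-taper line-noise regression and assumes
  stationary line interference.
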