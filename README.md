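# pulselock

Neural entrainment to musical pulse, measured end to end: from a raw
musical recording and multi-channel EEG to group-level statistics on
phase-locking at metrical frequencies.

When people listen to music, cortical activity phase-locks to the beat.
Quantifying that entrainment for *self-selected, naturalistic* music is
awkward because every recording has its own tempo: a 2.5 Hz pulse in one
song and a 1.7 Hz pulse in another put "the beat" at different places in
the spectrum. `pulselock` implements the full analysis chain that solves
this:

1. **Pulse detection** (`audiofeat`, `grfnn`) — the audio is middle-ear
   filtered, reduced to a complex-domain onset-strength signal, and fed to
   a gradient-frequency network of canonical Hopf oscillators
   (76 oscillators, log-spaced 0.25–8 Hz).  Oscillators near the pulse and
   its harmonic ratios gain amplitude; the pulse is the most salient
   frequency in the delta range (≤ 3.5 Hz), with a harmonic (≥ 3.5 Hz) and
   a subharmonic read off the same amplitude profile.  A recording enters
   the analysis only if it contains a **stable epoch**: the first interval
   of at least 2 minutes in which all three tracked frequencies stay
   within a few percent.
2. **Entrainment** (`eegprep`, `entrain`) — EEG is epoched, downsampled,
   re-referenced to the mastoids (TP9/TP10), band-passed 1–55 Hz with a
   60 Hz notch, and screened for bad channels.  Both the music's amplitude
   envelope and every EEG channel are decomposed with 65 complex Morlet
   wavelets (0.25–5 Hz, 15 bins/octave, 3–8 cycles), and for each channel
   *j* and wavelet *k* the phase-locking value

   $$\mathrm{PLV}_{j,k} = \Bigl|\, n^{-1} \sum_{t=1}^{n}
     e^{\,i\,(\theta^{(1)}_{k,t} - \theta^{(2)}_{j,k,t})} \Bigr|$$

   is the resultant length of the relative phase between envelope
   ($\theta^{(1)}$) and EEG ($\theta^{(2)}$); 0 = no phase relation,
   1 = perfect locking.
3. **Pulse normalization** (`entrain`) — each PLV spectrum is resampled
   onto a dimensionless metrical axis on which the detected pulse sits at
   **2**, its subharmonic at 1 and its first harmonic at 4 (off-levels
   1.5, 3, 5 serve as non-rhythmic controls), so recordings with different
   tempi average meaningfully.
4. **Group statistics** (`stats`) — grand-averaged PLVs per participant,
   nine 6-electrode cluster means, normal-approximation bootstrap CIs
   (10,000 resamples), a two-sample KS test on pulse-frequency
   distributions, and linear mixed-effects contrasts
   (level × group, and cluster × group × level with uncorrelated random
   slopes) with Holm-corrected p-values.

Because the recordings and EEG of such studies are not redistributable,
the package ships a first-class synthetic-data module (`synthgen`):
percussive music with controllable pulse (0.5–4 Hz, modal ~2 Hz), accent
structure and tempo jumps, plus 64-channel-style EEG whose channels lock
to the envelope at chosen metrical levels with controllable strength κ —
so the whole pipeline is testable against known ground truth.

## Worked example

```python
import numpy as np
from pulselock import (MusicSpec, gen_music, complex_onset_detect, run_bank,
                       find_stable_epoch, amplitude_envelope, gen_eeg,
                       build_wavelet_bank, wavelet_phase, compute_plv,
                       normalize_to_pulse, extract_levels)
from pulselock.synthgen import EEGSpec, uniform_coupling

music = gen_music(MusicSpec(pulse_freq=2.5, duration=180.0), seed=7)
epoch = find_stable_epoch(run_bank(complex_onset_detect(music.audio)))
print(f"pulse {epoch.estimate.pulse:.3f} Hz, epoch [{epoch.start:.0f}, {epoch.end:.0f}] s")

fs = 500.0
env = amplitude_envelope(music.audio, target_fs=fs)
chans = ("O1", "O2", "Oz", "PO3")
eeg = gen_eeg(env, EEGSpec(channels=chans, fs=fs,
                           coupling=uniform_coupling({"pulse": 0.6}, chans),
                           noise_scale=1.0, phase_jitter=0.5, seed=0), 2.5)
bank = build_wavelet_bank(fs=fs)
i0, i1 = int(epoch.start * fs), int(epoch.end * fs)
plv = compute_plv(wavelet_phase(env.values[i0:i1], bank, "envelope"),
                  wavelet_phase(eeg.data[:, i0:i1], bank, "eeg"),
                  freqs=bank.center_freqs)
norm = normalize_to_pulse(plv, bank, epoch.estimate.pulse)
curve = np.nanmean(norm.values, axis=0)
print(f"normalized PLV peak at u = {norm.axis[np.nanargmax(curve)]:.2f}")
levels = extract_levels(norm)
for u, v in zip(levels.levels, np.nanmean(levels.values, axis=0)):
    print(f"  level {u:>3}: PLV = {v:.3f}" if np.isfinite(v)
          else f"  level {u:>3}: outside measured band")
```

prints

```
pulse 2.520 Hz, epoch [0, 180] s
normalized PLV peak at u = 2.00
  level 1.0: PLV = 0.087
  level 1.5: PLV = 0.609
  level 2.0: PLV = 0.897
  level 3.0: PLV = 0.097
  level 4.0: outside measured band
  level 5.0: outside measured band
```

The network detects the 2.5 Hz pulse (on its 15-bins/octave grid:
2.520 Hz), the whole 3-minute recording is tempo-stable, and after pulse
normalization the phase-locking peak sits exactly at the pulse level
(u = 2), far above the off-pulse control (u = 3).  With a 2.5 Hz pulse the
harmonic levels (u = 4, 5) map above the 5 Hz wavelet ceiling and are
reported as missing rather than extrapolated.

Cohort-scale use goes through the CLI:

```
pulselock simulate --out cohort/ --n-per-group 16 --seed 1
pulselock analyze  --manifest cohort/manifest.json --out results/
pulselock stats    --in results/
```

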