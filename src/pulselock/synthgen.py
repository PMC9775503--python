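"""Synthetic music, EEG, and cohort generation with known ground truth.

Real stimuli in this problem are participant-selected commercial
recordings and their EEG responses, neither of which is redistributable;
the generator emulates the features the analysis consumes:

* percussive music with a controllable pulse frequency (0.5-4 Hz, modal
  ~2 Hz in natural music), a metrical accent cycle, and optional tempo
  drift or jumps;
* multi-channel EEG whose channels contain oscillatory components
  phase-locked to the music's amplitude envelope at the subharmonic,
  pulse, and harmonic frequencies with controllable coupling strength per
  channel, riding on 1/f background noise;
* whole cohorts (two age groups x participants x recordings) written to
  disk with a JSON manifest recording every ground-truth quantity.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal

from .audiofeat import AudioRecording, EnvelopeSignal
from .eegprep import EEGRecording
from .montage import CLUSTER_NAMES, DEFAULT_CHANNELS, ElectrodeClusters

LEVELS = ("sub", "pulse", "harmonic")

PULSE_RANGE = (0.5, 4.0)


@dataclass
class MusicSpec:
    """Percussive test-music description.

    ``tempo_profile`` is a piecewise-constant map time -> pulse frequency,
    given as (start_time, freq) breakpoints; empty means constant
    ``pulse_freq``.  ``meter`` is the accent cycle in beats per measure.
    """

    pulse_freq: float = 2.0
    duration: float = 180.0
    meter: int = 2
    tempo_profile: list[tuple[float, float]] = field(default_factory=list)
    click_timbre: str = "burst"
    noise_floor: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.meter < 1:
            raise ValueError("accent cycle must be >= 1 beat")
        if self.click_timbre not in ("click", "burst"):
            raise ValueError("click_timbre must be 'click' or 'burst'")
        for f in [self.pulse_freq] + [f for _, f in self.tempo_profile]:
            if not PULSE_RANGE[0] <= f <= PULSE_RANGE[1]:
                raise ValueError(f"pulse frequency {f} outside {PULSE_RANGE} Hz")

    def freq_at(self, t: float) -> float:
        f = self.pulse_freq
        for t0, ft in sorted(self.tempo_profile):
            if t >= t0:
                f = ft
        return f


@dataclass
class MusicRender:
    audio: AudioRecording
    onset_times: np.ndarray  # s, ground truth (as rendered, sample-exact)
    accented: np.ndarray  # bool per onset
    pulse_track: list[tuple[float, float]]  # (start_time, pulse_freq) steps


def gen_music(spec: MusicSpec, fs: float = 8000.0, seed: int | None = 0) -> MusicRender:
    """Render a percussive click/burst train with exact ground truth.

    Events are placed so the inter-onset interval at time t equals
    1 / tempo_profile(t); every ``meter``-th event is accented (louder).
    Events are 5-ms raised-cosine-windowed noise bursts (broadband, so
    onset detection is robust) or windowed tone pips (``click``).
    """
    rng = np.random.default_rng(seed)
    onsets: list[float] = []
    t = 0.0
    while t < spec.duration - 1e-9:
        onsets.append(t)
        t += 1.0 / spec.freq_at(t)
    if not onsets or (len(onsets) < 2 and spec.duration < 1.0 / spec.freq_at(0.0)):
        raise ValueError("duration too short to contain one beat")
    onset_samples = np.round(np.array(onsets) * fs).astype(int)
    onset_times = onset_samples / fs
    accented = (np.arange(len(onsets)) % spec.meter) == 0

    n = int(round(spec.duration * fs))
    x = np.zeros(n + int(0.01 * fs))
    burst_len = max(int(round(0.005 * fs)), 8)
    win = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(burst_len) / (burst_len - 1)))
    for s_idx, acc in zip(onset_samples, accented):
        amp = 1.0 if acc else 0.6
        if spec.click_timbre == "burst":
            ev = rng.standard_normal(burst_len) * win
        else:
            ev = np.sin(2 * np.pi * 1500.0 * np.arange(burst_len) / fs) * win
        x[s_idx : s_idx + burst_len] += amp * ev
    x = x[:n]
    if spec.noise_floor > 0:
        x = x + spec.noise_floor * rng.standard_normal(n)

    track = [(0.0, spec.pulse_freq)] if not spec.tempo_profile else sorted(spec.tempo_profile)
    if track[0][0] > 0.0:
        track = [(0.0, spec.pulse_freq)] + track
    return MusicRender(AudioRecording(x, fs), onset_times, accented, track)


@dataclass
class EEGSpec:
    """Synthetic EEG description.

    ``coupling`` maps (channel label, metrical level) -> phase-locking
    strength kappa (microvolt amplitude of the locked component);
    ``phase_jitter`` is the s.d. (radians) of a slow phase-noise process
    added to each locked component, and ``noise_exponent`` the 1/f slope of
    the background noise.
    """

    channels: tuple[str, ...] = DEFAULT_CHANNELS
    fs: float = 500.0
    coupling: dict[tuple[str, str], float] = field(default_factory=dict)
    noise_exponent: float = 1.0
    noise_scale: float = 1.0
    phase_jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        labels = {c.upper() for c in self.channels}
        for (ch, level), k in self.coupling.items():
            if ch.upper() not in labels:
                raise ValueError(f"unknown channel label {ch!r} in coupling map")
            if level not in LEVELS:
                raise ValueError(f"unknown metrical level {level!r}")
            if k < 0:
                raise ValueError("coupling strengths must be >= 0")


def uniform_coupling(
    kappa_by_level: dict[str, float], channels: tuple[str, ...] = DEFAULT_CHANNELS
) -> dict[tuple[str, str], float]:
    """Same kappa per level on every channel."""
    return {(ch, lv): k for ch in channels for lv, k in kappa_by_level.items()}


def _one_over_f(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    shape = np.zeros_like(f)
    shape[1:] = f[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _level_phase(env: np.ndarray, fs: float, f: float) -> np.ndarray:
    """Instantaneous phase of the envelope's narrowband component at f."""
    lo, hi = 0.75 * f, 1.3 * f
    sos = signal.butter(2, [lo, hi], btype="bandpass", fs=fs, output="sos")
    band = signal.sosfiltfilt(sos, env - env.mean())
    return np.angle(signal.hilbert(band))


def level_frequencies(pulse_freq: float, meter: int = 2) -> dict[str, float]:
    return {"sub": pulse_freq / max(meter, 2), "pulse": pulse_freq, "harmonic": 2.0 * pulse_freq}


def gen_eeg(
    envelope: EnvelopeSignal,
    spec: EEGSpec,
    pulse_freq: float,
    meter: int = 2,
    id: str = "",
) -> EEGRecording:
    """Synthesize EEG phase-locked to the envelope.

    Each channel is sum_level kappa(ch, level) * cos(phi_level(t) + jitter)
    plus 1/f noise, where phi_level is the instantaneous phase of the
    envelope's narrowband component at the level frequency.  Channels with
    kappa = 0 everywhere contain only noise; identical seeds give
    bit-identical output.
    """
    freqs = level_frequencies(pulse_freq, meter)
    if spec.fs <= 2.0 * max(freqs.values()):
        raise ValueError("EEG fs must exceed twice the highest generated frequency")
    if envelope.fs != spec.fs:
        ratio = envelope.fs / spec.fs
        if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
            raise ValueError("envelope fs must equal or be an integer multiple of EEG fs")
        env = signal.resample_poly(envelope.values, 1, int(round(ratio)))
    else:
        env = envelope.values
    n = env.size
    rng = np.random.default_rng(spec.seed)

    phases = {lv: _level_phase(env, spec.fs, f) for lv, f in freqs.items()}
    sos_slow = signal.butter(2, min(0.5, 0.45 * spec.fs / 2), btype="low", fs=spec.fs, output="sos")

    data = np.zeros((len(spec.channels), n))
    for c, ch in enumerate(spec.channels):
        for lv in LEVELS:
            k = spec.coupling.get((ch, lv), 0.0)
            if k <= 0:
                continue
            if spec.phase_jitter > 0:
                jit = signal.sosfiltfilt(sos_slow, rng.standard_normal(n))
                sd = jit.std()
                jit = jit / sd * spec.phase_jitter if sd > 0 else jit
            else:
                jit = 0.0
            data[c] += k * np.cos(phases[lv] + jit)
        if spec.noise_scale > 0:
            data[c] += spec.noise_scale * _one_over_f(rng, n, spec.noise_exponent)
    return EEGRecording(data, spec.fs, list(spec.channels), [], id)


@dataclass
class CohortSpec:
    """Two-group cohort design with per-recording ground truth.

    ``group_effect`` multiplies all OA couplings relative to YA;
    ``cluster_effect`` maps (group, cluster, level) -> extra multiplicative
    kappa modifier on that cluster's channels.  ``short_fraction`` renders
    that fraction of recordings at 90 s so they fail the 2-min stable-epoch
    rule, emulating study attrition.
    """

    n_per_group: int = 16
    recordings_per_participant: int = 6
    group_effect: float = 1.0
    cluster_effect: dict[tuple[str, str, str], float] | None = None
    seed: int = 0
    duration: float = 180.0
    audio_fs: float = 8000.0
    eeg_fs: float = 500.0
    base_kappa: dict[str, float] = field(
        default_factory=lambda: {"sub": 0.2, "pulse": 0.4, "harmonic": 0.2}
    )
    noise_scale: float = 1.0
    phase_jitter: float = 0.7
    short_fraction: float = 0.0
    meter: int = 2
    pulse_sigma: float = 0.3  # log-normal spread of sampled pulse frequencies
    kappa_cv: float = 0.2  # participant-level log-normal spread of coupling
    channels: tuple[str, ...] = DEFAULT_CHANNELS

    def __post_init__(self) -> None:
        if self.n_per_group < 1 or self.recordings_per_participant < 1:
            raise ValueError("counts must be >= 1")
        if self.group_effect < 0:
            raise ValueError("group_effect must be >= 0")
        for key, mod in (self.cluster_effect or {}).items():
            group, cluster, level = key
            if group not in ("YA", "OA") or cluster not in CLUSTER_NAMES or level not in LEVELS:
                raise ValueError(f"bad cluster_effect key {key}")
            if mod < 0:
                raise ValueError("kappa modifiers must be >= 0")


def sample_pulse_freq(rng: np.random.Generator, sigma: float = 0.3) -> float:
    """Log-normal pulse-frequency draw with mode 2 Hz, truncated to [0.5, 4].

    mode = exp(mu - sigma^2) = 2 fixes mu; out-of-range draws are redrawn.
    """
    mu = np.log(2.0) + sigma**2
    while True:
        f = float(rng.lognormal(mu, sigma))
        if PULSE_RANGE[0] <= f <= PULSE_RANGE[1]:
            return f


def _participant_coupling(
    spec: CohortSpec, group: str, clusters: ElectrodeClusters, mult: float = 1.0
) -> dict[tuple[str, str], float]:
    gmul = (1.0 if group == "YA" else spec.group_effect) * mult
    coupling: dict[tuple[str, str], float] = {}
    for ch in spec.channels:
        cl = clusters.cluster_of(ch)
        for lv, k in spec.base_kappa.items():
            mod = 1.0
            if spec.cluster_effect and cl is not None:
                mod = spec.cluster_effect.get((group, cl, lv), 1.0)
            coupling[(ch, lv)] = k * gmul * mod
    return coupling


def gen_cohort(spec: CohortSpec, out_dir: str | Path) -> Path:
    """Generate the full on-disk dataset; returns the manifest path.

    Layout: one WAV + one BrainVision triplet per recording, and
    ``manifest.json`` holding group labels, ground-truth pulse frequencies,
    durations and the complete kappa maps.
    """
    from . import io as plio
    from .audiofeat import amplitude_envelope

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)
    clusters = ElectrodeClusters()
    manifest: dict = {"seed": spec.seed, "eeg_fs": spec.eeg_fs, "participants": []}
    for group in ("YA", "OA"):
        for p in range(spec.n_per_group):
            pid = f"{group}{p + 1:02d}"
            pmult = float(np.exp(rng.normal(0.0, spec.kappa_cv)))
            coupling = _participant_coupling(spec, group, clusters, pmult)
            precs = []
            for r in range(spec.recordings_per_participant):
                rid = f"{pid}_r{r + 1}"
                pulse = sample_pulse_freq(rng, spec.pulse_sigma)
                short = bool(rng.random() < spec.short_fraction)
                dur = 90.0 if short else spec.duration
                mspec = MusicSpec(pulse_freq=pulse, duration=dur, meter=spec.meter)
                music = gen_music(mspec, fs=spec.audio_fs, seed=int(rng.integers(2**31)))
                env = amplitude_envelope(music.audio, target_fs=spec.eeg_fs)
                espec = EEGSpec(
                    channels=spec.channels,
                    fs=spec.eeg_fs,
                    coupling=coupling,
                    noise_scale=spec.noise_scale,
                    phase_jitter=spec.phase_jitter,
                    seed=int(rng.integers(2**31)),
                )
                eeg = gen_eeg(env, espec, pulse, spec.meter, id=rid)
                wav_path = out_dir / f"{rid}.wav"
                plio.write_wav(wav_path, music.audio)
                vhdr = plio.write_brainvision(out_dir / rid, eeg)
                precs.append(
                    {
                        "id": rid,
                        "wav": wav_path.name,
                        "vhdr": vhdr.name,
                        "pulse_freq": pulse,
                        "duration": dur,
                        "short": short,
                        "onset_times": [round(float(t), 6) for t in music.onset_times[:5]],
                        "n_onsets": int(music.onset_times.size),
                    }
                )
            manifest["participants"].append(
                {
                    "id": pid,
                    "group": group,
                    "recordings": precs,
                    "kappa": {f"{ch}|{lv}": k for (ch, lv), k in coupling.items()},
                }
            )
    mpath = out_dir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1), encoding="utf-8")
    return mpath


def gen_cohort_levels(
    spec: CohortSpec,
    n_samples: int = 500,
    level_pairs: dict[str, str] | None = None,
    seed: int | None = None,
):
    """Scaled phasor-model cohort: level-value table without audio rendering.

    For large replicate loops (power / type-I studies of the group
    statistics), each (participant, recording, channel, metrical level)
    cell is reduced to its narrowband physics: the relative phase between
    envelope and EEG is ``angle(kappa * exp(i*jitter_t) + noise * eps_t)``
    with ``eps_t`` complex standard Gaussian — a locked phasor of strength
    kappa in additive noise — and the PLV of that series is computed with
    the same estimator used on real data (:func:`pulselock.entrain.compute_plv`).
    Off-levels (kappa = 0) reduce to uniform relative phases, i.e. the
    estimator's chance floor at the given series length.

    Returns a long DataFrame (participant, group, recording, channel,
    level, plv) ready for :func:`pulselock.stats.grand_average` /
    :func:`pulselock.stats.fit_level_group_model`.
    """
    import pandas as pd

    from .entrain import PhaseSeries, compute_plv

    if level_pairs is None:
        level_pairs = {"pulse": "off_pulse", "sub": "off_subharmonic"}
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    clusters = ElectrodeClusters()
    channels = [c for c in spec.channels if clusters.cluster_of(c) is not None]
    level_names: list[tuple[str, str | None]] = []
    for lv, off in level_pairs.items():
        level_names.append((lv, lv))
        if off:
            level_names.append((off, None))  # off-levels carry no coupling
    L = len(level_names)
    rows = []
    for group in ("YA", "OA"):
        for p in range(spec.n_per_group):
            pid = f"{group}{p + 1:02d}"
            pmult = float(np.exp(rng.normal(0.0, spec.kappa_cv)))
            coupling = _participant_coupling(spec, group, clusters, pmult)
            for r in range(spec.recordings_per_participant):
                rel = np.empty((len(channels), L, n_samples))
                for c, ch in enumerate(channels):
                    for j, (name, src) in enumerate(level_names):
                        k = coupling.get((ch, src), 0.0) if src else 0.0
                        jit = rng.normal(0.0, spec.phase_jitter, n_samples)
                        eps = rng.normal(size=n_samples) + 1j * rng.normal(size=n_samples)
                        z = k * np.exp(1j * jit) + spec.noise_scale * eps / np.sqrt(2.0)
                        rel[c, j] = np.angle(z)
                ref = PhaseSeries(
                    np.zeros((L, n_samples)), np.ones((L, n_samples), bool), 1.0, "envelope"
                )
                obs = PhaseSeries(-rel, np.ones_like(rel, bool), 1.0, "eeg")
                plv = compute_plv(ref, obs)
                for c, ch in enumerate(channels):
                    for j, (name, _) in enumerate(level_names):
                        rows.append(
                            {
                                "participant": pid,
                                "group": group,
                                "recording": f"{pid}_r{r + 1}",
                                "channel": ch,
                                "level": name,
                                "plv": plv.values[c, j],
                            }
                        )
    return pd.DataFrame(rows)
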