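"""Gradient-frequency network of canonical Hopf oscillators for pulse and
meter estimation, plus the stable-epoch detector that gates recordings into
the entrainment analysis.

Each oscillator obeys (complex state z_i, natural frequency f_i in Hz)

    dz_i/dt = f_i * [ z_i * (alpha + i*2*pi + beta1*|z_i|^2
                             + eps*beta2*|z_i|^4 / (1 - eps*|z_i|^2))
                      + c * s(t) ]

with s(t) the rectified onset signal.  In the critical regime (alpha = 0,
beta1, beta2 < 0) the origin is marginally stable and oscillators near the
stimulus frequency and its harmonic ratios (1:2, 1:3, 2:1, ...) gain
amplitude, so the time-averaged |z_i| profile exposes the pulse, its
subharmonic and its harmonics.  A pulse is read off as the most salient
frequency at or below 3.5 Hz; a harmonic as the most salient near-integer
multiple at or above 3.5 Hz; a subharmonic as the most salient frequency
near pulse/2 or pulse/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audiofeat import OnsetSignal


def default_freq_grid(fmin: float = 0.25, fmax: float = 8.0, bins_per_octave: int = 15) -> np.ndarray:
    k = int(round(bins_per_octave * np.log2(fmax / fmin)))
    return fmin * 2.0 ** (np.arange(k + 1) / bins_per_octave)


@dataclass
class OscillatorBankParams:
    """Hopf-bank parameters; defaults put every oscillator at criticality."""

    freqs: np.ndarray = field(default_factory=default_freq_grid)
    alpha: float = 0.0
    beta1: float = -1.0
    beta2: float = -1.0
    eps: float = 0.5
    coupling: float = 1.0
    fs_int: float = 250.0  # integration rate, Hz (fixed-step RK4)
    store_decim: int = 10  # amplitudes stored at fs_int / store_decim

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("oscillator frequencies must be strictly increasing")
        if 1.0 / self.fs_int >= 1.0 / (2.0 * self.freqs[-1]):
            raise ValueError("integration step must be < 1/(2*max frequency)")


@dataclass
class OscillatorBankRun:
    amplitudes: np.ndarray  # (oscillators, time) |z_i(t)|
    freqs: np.ndarray  # Hz
    fs_amp: float  # amplitude sampling rate

    @property
    def duration(self) -> float:
        return self.amplitudes.shape[1] / self.fs_amp


@dataclass
class PulseEstimate:
    pulse: float
    subharmonic: float | None
    harmonic: float | None
    saliences: tuple[float, float | None, float | None]


@dataclass
class StableEpoch:
    start: float
    end: float
    estimate: PulseEstimate


class NoPulseError(ValueError):
    """Raised when the salience profile has no usable peak in the delta range."""


class BlowUpError(FloatingPointError):
    """Numerical blow-up of an oscillator (|z|^2 * eps reached 1)."""

    def __init__(self, osc_index: int, freq: float, t: float):
        super().__init__(
            f"oscillator {osc_index} ({freq:.3g} Hz) blew up at t={t:.2f} s"
        )
        self.osc_index = osc_index
        self.freq = freq
        self.t = t


def _drift(z: np.ndarray, s: float, f: np.ndarray, p: OscillatorBankParams) -> np.ndarray:
    a2 = np.abs(z) ** 2
    nl = p.alpha + 2j * np.pi + p.beta1 * a2 + p.eps * p.beta2 * a2**2 / (1.0 - p.eps * a2)
    return f * (z * nl + p.coupling * s)


def run_bank(onset: OnsetSignal, params: OscillatorBankParams | None = None) -> OscillatorBankRun:
    """Integrate the bank driven by the onset signal (fixed-step RK4).

    The onset series is linearly interpolated onto the integration grid and
    scaled so its 95th percentile is 1, which keeps the effective forcing
    comparable across recordings of different loudness.  Returns |z_i(t)|
    at ``fs_int / store_decim``.
    """
    p = params or OscillatorBankParams()
    if onset.duration < 10.0:
        raise ValueError("onset signal shorter than 10 s")
    dt = 1.0 / p.fs_int
    n_steps = int(np.floor(onset.duration * p.fs_int))
    # forcing on the RK4 half-step grid
    t_half = np.arange(2 * n_steps + 1) * (dt / 2.0)
    t_src = np.arange(onset.values.size) / onset.fs_frames
    s_half = np.interp(t_half, t_src, onset.values)
    scale = np.percentile(s_half[s_half > 0], 95) if np.any(s_half > 0) else 1.0
    if scale > 0:
        s_half = s_half / scale

    f = p.freqs
    z = np.full(f.size, 1e-3 + 0j)
    n_out = n_steps // p.store_decim + 1
    amps = np.empty((f.size, n_out))
    amps[:, 0] = np.abs(z)
    j = 1
    for i in range(n_steps):
        s0, sm, s1 = s_half[2 * i], s_half[2 * i + 1], s_half[2 * i + 2]
        k1 = _drift(z, s0, f, p)
        k2 = _drift(z + 0.5 * dt * k1, sm, f, p)
        k3 = _drift(z + 0.5 * dt * k2, sm, f, p)
        k4 = _drift(z + dt * k3, s1, f, p)
        z = z + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        a2 = np.abs(z) ** 2
        if np.any(p.eps * a2 >= 1.0) or not np.all(np.isfinite(z)):
            bad = int(np.argmax(np.where(np.isfinite(a2), p.eps * a2, np.inf)))
            raise BlowUpError(bad, float(f[bad]), (i + 1) * dt)
        if (i + 1) % p.store_decim == 0:
            amps[:, j] = np.sqrt(a2)
            j += 1
    return OscillatorBankRun(amps[:, :j], f.copy(), p.fs_int / p.store_decim)


def _salience(run: OscillatorBankRun, window: tuple[float, float]) -> np.ndarray:
    i0 = max(0, int(np.floor(window[0] * run.fs_amp)))
    i1 = min(run.amplitudes.shape[1], int(np.ceil(window[1] * run.fs_amp)))
    if i1 <= i0:
        raise ValueError("analysis window outside the run")
    return run.amplitudes[:, i0:i1].mean(axis=1)


def estimate_metrical_frequencies(
    run: OscillatorBankRun,
    window: tuple[float, float] | None = None,
    delta_max: float = 3.5,
    ratio_tol: float = 0.06,
    peak_margin: float = 0.5,
    peak_slack: float = 0.15,
) -> PulseEstimate:
    """Pulse, harmonic and subharmonic from the time-averaged amplitude profile.

    Salience is the mean |z_i| over the window.  The pulse is the most
    salient frequency <= ``delta_max`` (3.5 Hz, the delta/theta boundary,
    inclusive); it must be a local maximum of the profile exceeding the
    median salience by ``peak_margin`` (relative), otherwise a
    :class:`NoPulseError` is raised — a flat, noise-driven profile has no
    perceptible pulse.  The harmonic is the most salient frequency
    >= ``delta_max`` within ``ratio_tol`` of an integer multiple {2, 3, 4}
    of the pulse; the subharmonic the most salient near pulse/2 or pulse/3.
    Either may be absent (None).  Near-ties in salience break toward the
    lower frequency — among admissible peaks within ``peak_slack``
    (relative) of the most salient one, the slowest wins — favouring the
    slower pulse percept when a harmonic of the beat resonates about as
    strongly as the beat itself.
    """
    if window is None:
        window = (0.0, run.duration)
    sal = _salience(run, window)
    f = run.freqs
    delta = f <= delta_max + 1e-12
    if not np.any(delta):
        raise NoPulseError("no oscillators in the delta range")
    med = np.median(sal)
    admissible = []
    for i in np.flatnonzero(delta):
        left = sal[i - 1] if i > 0 else -np.inf
        right = sal[i + 1] if i < sal.size - 1 else -np.inf
        if sal[i] >= left and sal[i] >= right and sal[i] > (1.0 + peak_margin) * med:
            admissible.append(i)
    if not admissible:
        raise NoPulseError("no salient local maximum in the delta range")
    best = max(sal[i] for i in admissible)
    pulse_i = min(i for i in admissible if sal[i] >= (1.0 - peak_slack) * best)
    pulse = float(f[pulse_i])

    def best_candidate(targets: list[float], band: np.ndarray) -> tuple[float, float] | None:
        cand = np.zeros(f.size, dtype=bool)
        for tgt in targets:
            cand |= np.abs(f / tgt - 1.0) <= ratio_tol
        cand &= band
        if not np.any(cand):
            return None
        ci = np.flatnonzero(cand)
        best = ci[np.argmax(sal[ci])]
        return float(f[best]), float(sal[best])

    harm = best_candidate(
        [m * pulse for m in (2, 3, 4) if m * pulse >= delta_max - 1e-12],
        (f >= delta_max - 1e-12) & (np.arange(f.size) != pulse_i),
    )
    sub = best_candidate([pulse / 2.0, pulse / 3.0], f < pulse)
    return PulseEstimate(
        pulse,
        sub[0] if sub else None,
        harm[0] if harm else None,
        (float(sal[pulse_i]), sub[1] if sub else None, harm[1] if harm else None),
    )


def track_metrical_frequencies(
    run: OscillatorBankRun,
    window_len: float = 10.0,
    hop: float = 1.0,
    **est_kwargs,
) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window pulse/sub/harmonic tracks.

    Returns (window start times, 3 x n_windows array of frequencies, NaN
    where absent or no pulse was detected in that window).
    """
    starts = np.arange(0.0, run.duration - window_len + 1e-9, hop)
    tracks = np.full((3, starts.size), np.nan)
    for w, t0 in enumerate(starts):
        try:
            est = estimate_metrical_frequencies(run, (t0, t0 + window_len), **est_kwargs)
        except NoPulseError:
            continue
        tracks[0, w] = est.pulse
        tracks[1, w] = est.subharmonic if est.subharmonic is not None else np.nan
        tracks[2, w] = est.harmonic if est.harmonic is not None else np.nan
    return starts, tracks


def find_stable_epoch(
    run: OscillatorBankRun,
    min_len: float = 120.0,
    tol: float = 0.05,
    window_len: float = 10.0,
    hop: float = 1.0,
    **est_kwargs,
) -> StableEpoch | None:
    """Earliest interval of at least ``min_len`` seconds over which the
    tracked pulse, subharmonic and harmonic each stay within ``tol``
    (relative) of their interval median.

    The pulse track must be defined throughout the interval; subharmonic
    and harmonic tracks are checked only where defined.  Returns None when
    the run is shorter than ``min_len`` or no such interval exists — the
    recording is then excluded from the entrainment analysis.
    """
    if run.duration < min_len:
        return None
    starts, tracks = track_metrical_frequencies(run, window_len, hop, **est_kwargs)

    def stable(track: np.ndarray, require_all: bool) -> bool:
        vals = track[np.isfinite(track)]
        if vals.size == 0:
            return not require_all
        if require_all and vals.size != track.size:
            return False
        med = np.median(vals)
        return bool(np.all(np.abs(vals / med - 1.0) <= tol))

    n = starts.size
    for a in range(n):
        # longest stable extension from this start
        b_best = None
        for b in range(a, n):
            seg = tracks[:, a : b + 1]
            if stable(seg[0], True) and stable(seg[1], False) and stable(seg[2], False):
                b_best = b
            else:
                break
        if b_best is None:
            continue
        t0, t1 = starts[a], starts[b_best] + window_len
        if t1 - t0 >= min_len:
            est = estimate_metrical_frequencies(run, (t0, t1), **est_kwargs)
            return StableEpoch(float(t0), float(t1), est)
    return None
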