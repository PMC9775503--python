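"""Deterministic EEG preprocessing chain: epoching to the stimulation
period, downsampling, mastoid re-referencing, zero-phase band-pass plus
line-noise notch, and statistical bad-channel flagging.

Artifact correction stages that target biological artifacts (subspace
reconstruction, ICA, channel interpolation) are deliberately not part of
this chain; externally cleaned recordings can enter at this stage's output
contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal


@dataclass
class EEGRecording:
    """Channels x time EEG in microvolts, with channel labels and events."""

    data: np.ndarray
    fs: float
    labels: list[str]
    events: list[tuple[str, int]] = field(default_factory=list)
    id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("EEG data must be channels x time")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("label count does not match channel count")
        if len(set(l.upper() for l in self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for name, idx in self.events:
            if not 0 <= idx < self.data.shape[1]:
                raise ValueError(f"event {name!r} at sample {idx} out of range")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def channel(self, label: str) -> np.ndarray:
        lab = [l.upper() for l in self.labels]
        try:
            return self.data[lab.index(label.upper())]
        except ValueError:
            raise KeyError(f"channel {label!r} not present") from None


def epoch_to_stimulation(
    eeg: EEGRecording,
    start_prefix: str = "start",
    end_prefix: str = "end",
    margin: float = 1.0,
) -> EEGRecording:
    """Trim to [first start event - margin, last end event + margin],
    inclusive at both endpoints; event indices are shifted accordingly."""
    starts = [i for (n, i) in eeg.events if n.lower().startswith(start_prefix)]
    ends = [i for (n, i) in eeg.events if n.lower().startswith(end_prefix)]
    if not starts or not ends:
        raise ValueError(
            f"missing events: need labels starting with {start_prefix!r} and {end_prefix!r}"
        )
    pad = int(round(margin * eeg.fs))
    i0 = min(starts) - pad
    i1 = max(ends) + pad
    if i0 < 0 or i1 >= eeg.n_samples:
        raise ValueError("stimulation period leaves less than the margin at a recording edge")
    events = [(n, i - i0) for (n, i) in eeg.events if i0 <= i <= i1]
    return EEGRecording(eeg.data[:, i0 : i1 + 1].copy(), eeg.fs, list(eeg.labels), events, eeg.id)


def resample(eeg: EEGRecording, new_fs: float = 1000.0) -> EEGRecording:
    """Anti-alias polyphase downsampling to ``new_fs`` (no upsampling)."""
    if new_fs > eeg.fs:
        raise ValueError("upsampling not supported")
    if new_fs == eeg.fs:
        return eeg
    frac = Fraction(new_fs / eeg.fs).limit_denominator(10000)
    data = signal.resample_poly(eeg.data, frac.numerator, frac.denominator, axis=1)
    ratio = new_fs / eeg.fs
    events = [(n, min(int(round(i * ratio)), data.shape[1] - 1)) for (n, i) in eeg.events]
    return EEGRecording(data, new_fs, list(eeg.labels), events, eeg.id)


def rereference_mastoids(
    eeg: EEGRecording, refs: tuple[str, str] = ("TP9", "TP10")
) -> EEGRecording:
    """Subtract the mean of the bilateral mastoid channels from every
    channel, then drop the reference channels from the analysis set."""
    lab_u = [l.upper() for l in eeg.labels]
    for r in refs:
        if r.upper() not in lab_u:
            raise ValueError(f"reference channel {r} not present")
    ref = np.mean([eeg.channel(r) for r in refs], axis=0)
    keep = [i for i, l in enumerate(lab_u) if l not in (r.upper() for r in refs)]
    data = eeg.data[keep] - ref[None, :]
    labels = [eeg.labels[i] for i in keep]
    return EEGRecording(data, eeg.fs, labels, list(eeg.events), eeg.id)


def _bandpass_fir(fs: float, hp: float, lp: float) -> np.ndarray:
    # windowed-sinc FIR, Hamming window, transition width 25% of the
    # (narrower) high-pass cutoff; odd length => exactly zero-phase when
    # applied centred
    trans = 0.25 * hp
    numtaps = int(np.ceil(3.3 * fs / trans))
    numtaps += 1 - numtaps % 2
    return signal.firwin(numtaps, [hp, lp], pass_zero=False, window="hamming", fs=fs)


def bandpass_and_notch(
    eeg: EEGRecording,
    hp: float = 1.0,
    lp: float = 55.0,
    line: float = 60.0,
    notch_q: float = 30.0,
) -> EEGRecording:
    """Zero-phase FIR band-pass (removes DC and slow drift, caps at ``lp``)
    followed by a zero-phase IIR notch at the line frequency."""
    if lp >= eeg.fs / 2:
        raise ValueError("low-pass cutoff must be below Nyquist")
    h = _bandpass_fir(eeg.fs, hp, lp)
    data = signal.fftconvolve(eeg.data, h[None, :], mode="same", axes=1)
    if line < eeg.fs / 2:
        b, a = signal.iirnotch(line, notch_q, fs=eeg.fs)
        data = signal.filtfilt(b, a, data, axis=1)
    return EEGRecording(data, eeg.fs, list(eeg.labels), list(eeg.events), eeg.id)


def flag_bad_channels(eeg: EEGRecording, z: float = 5.0, n_bins: int = 100) -> list[str]:
    """Joint-probability bad-channel flagging.

    Each channel's samples are scored by their mean negative log-probability
    under the pooled amplitude distribution of all channels (histogram
    density); scores are normalized to leave-one-out z-scores across
    channels and any channel exceeding ``z`` is flagged.  Channels sharing
    the ensemble statistics score near zero; a channel with grossly
    inflated variance or amplitude outliers scores high.
    """
    if eeg.data.shape[0] < 8:
        raise ValueError("need at least 8 channels for a stable ensemble estimate")
    pooled = eeg.data.ravel()
    scale = np.std(pooled)
    if scale == 0:
        return []
    lo, hi = pooled.min(), pooled.max()
    hist, edges = np.histogram(pooled, bins=n_bins, range=(lo, hi), density=True)
    floor = 1.0 / (pooled.size * (hi - lo))
    dens = np.maximum(hist, floor)
    scores = np.empty(eeg.data.shape[0])
    for c, row in enumerate(eeg.data):
        idx = np.clip(np.searchsorted(edges, row, side="right") - 1, 0, n_bins - 1)
        scores[c] = -np.mean(np.log(dens[idx]))
    flagged = []
    for c in range(scores.size):
        others = np.delete(scores, c)
        sd = others.std()
        if sd == 0:
            continue
        if (scores[c] - others.mean()) / sd > z:
            flagged.append(eeg.labels[c])
    return flagged


def preprocess(
    eeg: EEGRecording,
    new_fs: float = 1000.0,
    hp: float = 1.0,
    lp: float = 55.0,
    line: float = 60.0,
    bad_z: float = 5.0,
    epoch: bool = True,
) -> tuple[EEGRecording, list[str]]:
    """Full deterministic chain; returns the cleaned recording and the list
    of flagged bad channels (dropped from the output)."""
    out = epoch_to_stimulation(eeg) if epoch and eeg.events else eeg
    out = resample(out, new_fs)
    out = rereference_mastoids(out)
    out = bandpass_and_notch(out, hp, lp, line)
    bad = flag_bad_channels(out, bad_z) if out.data.shape[0] >= 8 else []
    if bad:
        keep = [i for i, l in enumerate(out.labels) if l not in bad]
        out = EEGRecording(
            out.data[keep], out.fs, [out.labels[i] for i in keep], list(out.events), out.id
        )
    return out, bad
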