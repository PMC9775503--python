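"""Orchestration: per-recording fan-out (audio -> pulse/epoch -> envelope
-> EEG preprocessing -> PLV -> pulse normalization -> metrical levels) and
cohort-level fan-in to the group statistics."""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict

from . import audiofeat, eegprep, entrain, grfnn, io as plio, stats as plstats
from .audiofeat import AudioRecording, StftParams
from .eegprep import EEGRecording

log = logging.getLogger("pulselock")


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class StftConfig(_Block):
    win_s: float = 0.046
    hop_s: float = 0.0116
    window: str = "hann"


class EnvelopeConfig(_Block):
    method: str = "hilbert"
    lowpass_hz: float = 50.0


class OscillatorConfig(_Block):
    fmin: float = 0.25
    fmax: float = 8.0
    bins_per_octave: int = 15
    alpha: float = 0.0
    beta1: float = -1.0
    beta2: float = -1.0
    eps: float = 0.5
    coupling: float = 1.0
    fs_int: float = 250.0

    def params(self) -> grfnn.OscillatorBankParams:
        return grfnn.OscillatorBankParams(
            freqs=grfnn.default_freq_grid(self.fmin, self.fmax, self.bins_per_octave),
            alpha=self.alpha,
            beta1=self.beta1,
            beta2=self.beta2,
            eps=self.eps,
            coupling=self.coupling,
            fs_int=self.fs_int,
        )


class StabilityConfig(_Block):
    min_len: float = 120.0
    tol: float = 0.05
    window_len: float = 10.0
    hop: float = 1.0
    # pulse-selection rule of the windowed estimator
    peak_margin: float = 0.5
    peak_slack: float = 0.15
    ratio_tol: float = 0.06


class WaveletConfig(_Block):
    fmin: float = 0.25
    fmax: float = 5.0
    bins_per_octave: int = 15


class BootstrapConfig(_Block):
    n_boot: int = 10000
    level: float = 0.95


class RunConfig(_Block):
    """Validated run configuration; unknown keys are rejected."""

    seed: int = 0
    alpha: float = 0.05
    analysis_fs: float = 500.0
    stft: StftConfig = StftConfig()
    envelope: EnvelopeConfig = EnvelopeConfig()
    oscillator: OscillatorConfig = OscillatorConfig()
    stability: StabilityConfig = StabilityConfig()
    wavelets: WaveletConfig = WaveletConfig()
    bootstrap: BootstrapConfig = BootstrapConfig()
    keep_intermediates: bool = False

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls.model_validate(json.loads(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def run_recording(
    audio: AudioRecording,
    eeg: EEGRecording,
    config: RunConfig | None = None,
    recording_id: str = "",
) -> dict:
    """Full per-recording chain.

    Returns a dict with ``survived``: on success it carries the pulse
    estimate, stable-epoch bounds and a per-channel level table; on
    exclusion (no stable epoch, or a stage error) a machine-readable
    reason.
    """
    cfg = config or RunConfig()
    rid = recording_id or audio.id or eeg.id
    try:
        onset = audiofeat.complex_onset_detect(
            audio, StftParams(cfg.stft.win_s, cfg.stft.hop_s, cfg.stft.window)
        )
        run = grfnn.run_bank(onset, cfg.oscillator.params())
        epoch = grfnn.find_stable_epoch(
            run,
            min_len=cfg.stability.min_len,
            tol=cfg.stability.tol,
            window_len=cfg.stability.window_len,
            hop=cfg.stability.hop,
            peak_margin=cfg.stability.peak_margin,
            peak_slack=cfg.stability.peak_slack,
            ratio_tol=cfg.stability.ratio_tol,
        )
        if epoch is None:
            reason = (
                "epoch shorter than stability minimum"
                if run.duration < cfg.stability.min_len
                else "no stable epoch found"
            )
            return {"id": rid, "survived": False, "reason": reason}
        pulse = epoch.estimate.pulse

        fs = min(cfg.analysis_fs, eeg.fs)
        env = audiofeat.amplitude_envelope(
            audio, target_fs=fs, lowpass_hz=min(cfg.envelope.lowpass_hz, 0.45 * fs),
            method=cfg.envelope.method,
        )
        clean, bad = eegprep.preprocess(
            eeg, new_fs=fs, lp=min(55.0, 0.45 * fs), line=60.0, epoch=bool(eeg.events)
        )
        i0 = int(epoch.start * fs)
        i1 = int(epoch.end * fs)
        n = min(env.values.size, clean.n_samples, i1)
        env_seg = env.values[i0:n]
        eeg_seg = clean.data[:, i0:n]

        bank = entrain.build_wavelet_bank(
            cfg.wavelets.fmin, cfg.wavelets.fmax, cfg.wavelets.bins_per_octave, fs
        )
        env_phase = entrain.wavelet_phase(env_seg, bank, source="envelope")
        eeg_phase = entrain.wavelet_phase(eeg_seg, bank, source="eeg")
        plv = entrain.compute_plv(env_phase, eeg_phase, freqs=bank.center_freqs)
        norm = entrain.normalize_to_pulse(plv, bank, pulse, cfg.wavelets.bins_per_octave)
        levels = entrain.extract_levels(norm)

        rows = []
        for c, ch in enumerate(clean.labels):
            for j, u in enumerate(levels.levels):
                rows.append(
                    {
                        "recording": rid,
                        "channel": ch,
                        "level": entrain.LEVEL_NAMES[float(u)],
                        "level_u": float(u),
                        "plv": levels.values[c, j],
                    }
                )
        return {
            "id": rid,
            "survived": True,
            "pulse": pulse,
            "subharmonic": epoch.estimate.subharmonic,
            "harmonic": epoch.estimate.harmonic,
            "epoch_start": epoch.start,
            "epoch_end": epoch.end,
            "bad_channels": bad,
            "levels": pd.DataFrame(rows),
            "normalized": norm,
        }
    except Exception as exc:  # any stage error excludes the recording
        log.warning("recording %s excluded: %s", rid, exc)
        return {"id": rid, "survived": False, "reason": f"{type(exc).__name__}: {exc}"}


def run_cohort(manifest_path: str | Path, config: RunConfig | None = None,
               out_dir: str | Path | None = None) -> dict:
    """Analyze a generated cohort end to end; returns the run report.

    Fan-out over recordings (results independent of order), fan-in to the
    statistics: pulse-frequency KS test between groups, grand-averaged
    level contrasts, cluster-level contrasts, bootstrap CIs.  Output
    tables are written to ``out_dir`` when given, each stamped with the
    config hash.
    """
    cfg = config or RunConfig()
    manifest_path = Path(manifest_path)
    manifest = json.loads(manifest_path.read_text())
    base = manifest_path.parent
    chash = cfg.hash()

    level_rows = []
    survival = []
    pulse_by_group: dict[str, list[float]] = {"YA": [], "OA": []}
    for part in manifest["participants"]:
        for rec in part["recordings"]:
            audio = plio.read_wav(base / rec["wav"])
            eeg = plio.read_brainvision(base / rec["vhdr"])
            res = run_recording(audio, eeg, cfg, rec["id"])
            survival.append(
                {
                    "id": rec["id"],
                    "participant": part["id"],
                    "group": part["group"],
                    "survived": res["survived"],
                    "reason": res.get("reason", ""),
                    "pulse": res.get("pulse"),
                    "subharmonic": res.get("subharmonic"),
                    "harmonic": res.get("harmonic"),
                    "epoch_start": res.get("epoch_start"),
                    "epoch_end": res.get("epoch_end"),
                }
            )
            if cfg.keep_intermediates and out_dir is not None and res["survived"]:
                inter = Path(out_dir) / "intermediates"
                inter.mkdir(parents=True, exist_ok=True)
                plio.write_long_table(inter / f"{rec['id']}_levels.tsv", res["levels"], chash)
            if not res["survived"]:
                continue
            pulse_by_group[part["group"]].append(res["pulse"])
            tab = res["levels"].copy()
            tab["participant"] = part["id"]
            tab["group"] = part["group"]
            level_rows.append(tab)

    report: dict = {
        "config_hash": chash,
        "n_recordings": len(survival),
        "n_survived": int(sum(s["survived"] for s in survival)),
        "survival": survival,
        "by_group": {
            g: int(sum(s["survived"] for s in survival if s["group"] == g))
            for g in ("YA", "OA")
        },
    }
    if not level_rows:
        report["stats"] = "skipped: no surviving recordings"
        if out_dir is not None:
            _write_report(out_dir, report, chash)
        return report

    levels_long = pd.concat(level_rows, ignore_index=True)
    ga = plstats.grand_average(levels_long)
    cm_part = plstats.cluster_means(levels_long)

    results: dict = {}
    if all(pulse_by_group[g] for g in ("YA", "OA")):
        D, p = plstats.ks_two_sample(pulse_by_group["YA"], pulse_by_group["OA"])
        results["ks_pulse_freq"] = {"D": D, "p": p}

    pair = ga[ga["level"].isin(["pulse", "off_pulse"])]
    if pair["level"].nunique() == 2 and pair["group"].nunique() == 2:
        grand = plstats.fit_level_group_model(pair, include_cluster=False, alpha=cfg.alpha)
        results["grand_model"] = grand.table.to_dict("records")
        cpair = cm_part[cm_part["level"].isin(["pulse", "off_pulse"])]
        try:
            clus = plstats.fit_level_group_model(cpair, include_cluster=True, alpha=cfg.alpha)
            results["cluster_model"] = clus.table.to_dict("records")
        except RuntimeError as exc:
            results["cluster_model"] = f"not fitted: {exc}"

    cis = {}
    for (g, lv), sub in ga.groupby(["group", "level"]):
        if sub.shape[0] >= 2:
            lo, hi = plstats.bootstrap_ci(
                sub["plv"].to_numpy(), cfg.bootstrap.n_boot, cfg.bootstrap.level,
                seed=cfg.seed,
            )
            cis[f"{g}|{lv}"] = {"mean": float(sub["plv"].mean()), "lo": lo, "hi": hi}
    results["bootstrap_ci"] = cis
    report["stats"] = results

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        plio.write_long_table(out_dir / "levels_long.tsv", levels_long, chash)
        plio.write_long_table(out_dir / "grand_average.tsv", ga, chash)
        plio.write_long_table(out_dir / "cluster_means.tsv", cm_part, chash)
        _write_report(out_dir, report, chash)
    return report


def _write_report(out_dir: str | Path, report: dict, chash: str) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "run_report.json").write_text(json.dumps(report, indent=1, default=str))
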