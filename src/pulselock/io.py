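"""File I/O: WAV audio, BrainVision-style EEG triplets, delimited EEG
matrices, and the long-format level tables exchanged with the stats stage.

The BrainVision writer emits the minimal header/marker/binary triplet
(multiplexed little-endian IEEE float32) that standard EEG readers accept;
the reader parses the same dialect.
"""

from __future__ import annotations

import configparser
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .audiofeat import AudioRecording
from .eegprep import EEGRecording


# -- audio ---------------------------------------------------------------

def write_wav(path: str | Path, audio: AudioRecording, dtype: str = "int16") -> None:
    x = audio.samples
    peak = np.max(np.abs(x)) or 1.0
    if dtype == "int16":
        data = np.round(x / peak * 32766).astype(np.int16)
    elif dtype == "float32":
        data = (x / peak).astype(np.float32)
    else:
        raise ValueError(f"unsupported WAV dtype {dtype!r}")
    wavfile.write(str(path), int(audio.fs), data)


def read_wav(path: str | Path) -> AudioRecording:
    fs, data = wavfile.read(str(path))
    if data.ndim == 2:  # average to mono
        data = data.mean(axis=1)
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / np.iinfo(data.dtype).max
    else:
        data = data.astype(float)
    return AudioRecording(data, float(fs), Path(path).stem)


# -- BrainVision-style triplet -------------------------------------------

def write_brainvision(base: str | Path, eeg: EEGRecording) -> Path:
    """Write <base>.vhdr / <base>.vmrk / <base>.eeg; returns the header path."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    n_ch = len(eeg.labels)
    sampling_interval_us = 1e6 / eeg.fs
    hdr = ["BrainVision Data Exchange Header File Version 1.0", ""]
    hdr += [
        "[Common Infos]",
        f"DataFile={base.name}.eeg",
        f"MarkerFile={base.name}.vmrk",
        "DataFormat=BINARY",
        "DataOrientation=MULTIPLEXED",
        f"NumberOfChannels={n_ch}",
        f"SamplingInterval={sampling_interval_us:.6f}",
        "",
        "[Binary Infos]",
        "BinaryFormat=IEEE_FLOAT_32",
        "",
        "[Channel Infos]",
    ]
    hdr += [f"Ch{i + 1}={lab},,1,µV" for i, lab in enumerate(eeg.labels)]
    (base.parent / f"{base.name}.vhdr").write_text("\n".join(hdr) + "\n", encoding="utf-8")

    mrk = [
        "BrainVision Data Exchange Marker File Version 1.0",
        "",
        "[Common Infos]",
        f"DataFile={base.name}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0",
    ]
    for j, (name, idx) in enumerate(eeg.events, start=2):
        mrk.append(f"Mk{j}=Stimulus,{name},{idx + 1},1,0")
    (base.parent / f"{base.name}.vmrk").write_text("\n".join(mrk) + "\n", encoding="utf-8")

    flat = eeg.data.T.astype("<f4").ravel()  # multiplexed: sample-major
    flat.tofile(base.parent / f"{base.name}.eeg")
    return base.parent / f"{base.name}.vhdr"


def _parse_ini(text: str) -> configparser.ConfigParser:
    cp = configparser.ConfigParser(strict=False)
    cp.optionxform = str  # keep key case
    # strip the non-INI banner line
    body = "\n".join(l for l in text.splitlines() if not l.startswith("BrainVision"))
    cp.read_file(_io.StringIO(body))
    return cp


def read_brainvision(vhdr_path: str | Path) -> EEGRecording:
    vhdr_path = Path(vhdr_path)
    cp = _parse_ini(vhdr_path.read_text(encoding="utf-8"))
    common = cp["Common Infos"]
    if common.get("DataFormat", "BINARY") != "BINARY":
        raise ValueError("only BINARY BrainVision data is supported")
    if common.get("DataOrientation", "MULTIPLEXED") != "MULTIPLEXED":
        raise ValueError("only MULTIPLEXED orientation is supported")
    fmt = cp["Binary Infos"].get("BinaryFormat", "IEEE_FLOAT_32")
    dtype = {"IEEE_FLOAT_32": "<f4", "INT_16": "<i2"}.get(fmt)
    if dtype is None:
        raise ValueError(f"unsupported BinaryFormat {fmt}")
    n_ch = int(common["NumberOfChannels"])
    fs = 1e6 / float(common["SamplingInterval"])
    labels = []
    for i in range(n_ch):
        labels.append(cp["Channel Infos"][f"Ch{i + 1}"].split(",")[0])
    raw = np.fromfile(vhdr_path.parent / common["DataFile"], dtype=dtype)
    data = raw.reshape(-1, n_ch).T.astype(float)

    events: list[tuple[str, int]] = []
    mrk_path = vhdr_path.parent / common["MarkerFile"]
    if mrk_path.exists():
        mcp = _parse_ini(mrk_path.read_text(encoding="utf-8"))
        for key, val in mcp["Marker Infos"].items():
            parts = val.split(",")
            if parts[0] == "New Segment":
                continue
            events.append((parts[1], int(parts[2]) - 1))
    return EEGRecording(data, fs, labels, events, vhdr_path.stem)


# -- delimited fallback ---------------------------------------------------

def write_eeg_tsv(path: str | Path, eeg: EEGRecording) -> None:
    """Channels x time table: first column the label, then one column per
    sample; a leading comment line carries the sampling rate and events."""
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        ev = ";".join(f"{n}:{i}" for n, i in eeg.events)
        fh.write(f"# fs={eeg.fs} events={ev}\n")
        for lab, row in zip(eeg.labels, eeg.data):
            fh.write(lab + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def read_eeg_tsv(path: str | Path) -> EEGRecording:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().strip()
        if not header.startswith("#"):
            raise ValueError("missing header line with fs=")
        meta = dict(
            kv.split("=", 1) for kv in header.lstrip("# ").split(" ") if "=" in kv
        )
        fs = float(meta["fs"])
        events = []
        if meta.get("events"):
            for item in meta["events"].split(";"):
                name, idx = item.rsplit(":", 1)
                events.append((name, int(idx)))
        labels, rows = [], []
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            labels.append(parts[0])
            rows.append(np.array(parts[1:], dtype=float))
    return EEGRecording(np.vstack(rows), fs, labels, events, path.stem)


# -- long-format tables ---------------------------------------------------

def write_series_tsv(path: str | Path, t: np.ndarray, values: np.ndarray) -> None:
    """Two-column (time, value) table for envelope/onset signals."""
    np.savetxt(path, np.column_stack([t, values]), delimiter="\t", fmt="%.8g",
               header="time\tvalue", comments="")


def write_long_table(path: str | Path, frame: pd.DataFrame, config_hash: str = "") -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        if config_hash:
            fh.write(f"# config_hash={config_hash}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_long_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
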