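"""Electrode clusters and the default channel set.

Nine clusters of six 10-20-system channels each, as used in
auditory-related EEG work, cover 54 scalp electrodes; TP9/TP10 are the
bilateral mastoid reference pair and are not assigned to any cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field

ELECTRODE_CLUSTERS: dict[str, tuple[str, ...]] = {
    "LF": ("AF7", "AF3", "F7", "F5", "F3", "F1"),
    "RF": ("AF4", "AF8", "F2", "F4", "F6", "F8"),
    "LC": ("FT7", "FC5", "FC3", "T7", "C5", "C3"),
    "MC": ("FC1", "FCz", "FC2", "C1", "Cz", "C2"),
    "RC": ("FC4", "FC6", "FC8", "C4", "C6", "T8"),
    "LP": ("TP7", "CP5", "CP3", "P7", "P5", "P3"),
    "MP": ("CP1", "CPz", "CP2", "P1", "Pz", "P2"),
    "RP": ("CP4", "CP6", "CP8", "P4", "P6", "P8"),
    "O": ("PO3", "POz", "PO4", "O1", "Oz", "O2"),
}

CLUSTER_NAMES: tuple[str, ...] = tuple(ELECTRODE_CLUSTERS)

REFERENCE_CHANNELS: tuple[str, str] = ("TP9", "TP10")

#: 54 clustered scalp channels + the mastoid reference pair
DEFAULT_CHANNELS: tuple[str, ...] = tuple(
    ch for chans in ELECTRODE_CLUSTERS.values() for ch in chans
) + REFERENCE_CHANNELS


@dataclass
class ElectrodeClusters:
    """Validated cluster -> channels mapping (9 clusters x 6 channels)."""

    clusters: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(ELECTRODE_CLUSTERS)
    )

    def __post_init__(self) -> None:
        all_ch = [c.upper() for chans in self.clusters.values() for c in chans]
        if len(all_ch) != len(set(all_ch)):
            raise ValueError("a channel appears in two clusters")
        if any(len(chans) == 0 for chans in self.clusters.values()):
            raise ValueError("empty cluster")

    def cluster_of(self, channel: str) -> str | None:
        cu = channel.upper()
        for name, chans in self.clusters.items():
            if cu in (c.upper() for c in chans):
                return name
        return None

    def __iter__(self):
        return iter(self.clusters.items())
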