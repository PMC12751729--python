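"""Core containers shared across the pipeline.

The study montage is the 19-electrode international 10-20 layout with the
legacy temporal labels (T3/T4/T5/T6).  All downstream feature tables index
channels in the fixed order given by :data:`CHANNELS_1020`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: The 19 scalp electrodes of the study montage, in canonical order.
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

#: Modern 10-10 synonyms mapped back to the legacy temporal labels.
CHANNEL_SYNONYMS: dict[str, str] = {"T7": "T3", "T8": "T4", "P7": "T5", "P8": "T6"}


def normalize_channel_label(label: str) -> str:
    """Map a channel label onto the study's nomenclature.

    Strips common reference suffixes (``-REF``, ``-LE``), normalizes case
    (``FP1`` -> ``Fp1``), and converts 10-10 temporal synonyms
    (T7->T3, T8->T4, P7->T5, P8->T6).
    """
    lab = label.strip()
    for suffix in ("-REF", "-LE", "-AVG", "-A1", "-A2"):
        if lab.upper().endswith(suffix):
            lab = lab[: -len(suffix)]
    lab = lab.strip()
    canonical = {c.upper(): c for c in CHANNELS_1020}
    synonyms = {k.upper(): v for k, v in CHANNEL_SYNONYMS.items()}
    key = lab.upper()
    if key in canonical:
        return canonical[key]
    if key in synonyms:
        return synonyms[key]
    raise ValueError(f"unrecognized channel label: {label!r}")


@dataclass
class Recording:
    """One subject's continuous multichannel EEG in microvolts."""

    subject_id: str
    data: np.ndarray          # channels x samples, µV
    fs: float                 # Hz
    channels: tuple[str, ...] = CHANNELS_1020

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.channels = tuple(self.channels)
        if self.data.ndim != 2:
            raise ValueError("data must be a channels x samples matrix")
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} rows but {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.n_samples / self.fs

    def validate_montage(self) -> None:
        """Check the full 19-channel 10-20 montage and >=180 s duration."""
        if set(self.channels) != set(CHANNELS_1020):
            missing = set(CHANNELS_1020) - set(self.channels)
            extra = set(self.channels) - set(CHANNELS_1020)
            raise ValueError(f"montage mismatch: missing={missing}, extra={extra}")
        if self.duration < 180.0:
            raise ValueError(
                f"recording {self.subject_id}: duration {self.duration:.1f} s < 180 s"
            )

    def copy(self) -> "Recording":
        return Recording(self.subject_id, self.data.copy(), self.fs, self.channels)


@dataclass
class EpochSet:
    """Fixed-length epochs for one subject (epochs x channels x samples)."""

    subject_id: str
    epochs: np.ndarray
    fs: float
    epoch_length: float
    channels: tuple[str, ...] = CHANNELS_1020
    selected_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self) -> None:
        self.epochs = np.asarray(self.epochs, dtype=float)
        self.channels = tuple(self.channels)
        self.selected_indices = np.asarray(self.selected_indices, dtype=int)
        if self.epochs.ndim != 3:
            raise ValueError("epochs must be epochs x channels x samples")
        expected = int(round(self.epoch_length * self.fs))
        if self.epochs.shape[2] != expected:
            raise ValueError(
                f"epoch length {self.epoch_length} s at {self.fs} Hz implies "
                f"{expected} samples, got {self.epochs.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [lo, hi) in Hz; the top band is closed at 55 Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(f"invalid band {self.name}: [{self.lo}, {self.hi})")


#: The five analysis bands partitioning the 1-55 Hz range.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 12.0, 30.0),
    BandDefinition("gamma", 30.0, 55.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str) -> BandDefinition:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise ValueError(f"unknown band name: {name!r} (expected one of {BAND_NAMES})")
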