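"""Welch power spectra and relative band power features.

Each 2-s epoch is one Hamming-windowed Welch segment (no sub-segmentation,
no overlap), giving a 0.5 Hz bin spacing that resolves every band edge.
Relative power is reported in percent of total power over the 1-55 Hz
analysis range, per channel plus a "Global" channel-mean column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import DEFAULT_BANDS, BandDefinition, EpochSet

__all__ = ["welch_psd", "relative_band_power", "SpectralFeatures", "spectral_feature_row"]

GLOBAL = "Global"


@dataclass
class SpectralFeatures:
    """Relative band power (percent) per band and location.

    ``rel_power`` is a DataFrame: rows = band names, columns = the 19
    channels plus "Global" (the arithmetic mean over channels).  Columns
    sum to 100 over bands.
    """

    subject_id: str
    rel_power: pd.DataFrame


def welch_psd(es: EpochSet) -> tuple[np.ndarray, np.ndarray]:
    """Welch PSD per channel, one modified periodogram per epoch.

    Returns ``(freqs, psd)`` with ``psd`` of shape channels x bins in
    µV²/Hz (one-sided density).  Bin spacing is ``1 / epoch_length``.
    """
    if es.n_epochs < 1:
        raise ValueError("need at least one epoch")
    nper = es.epochs.shape[2]
    window = np.hamming(nper)
    # window power normalization for the modified periodogram
    norm = es.fs * np.sum(window**2)
    spec = np.fft.rfft(es.epochs * window, axis=2)
    psd = (np.abs(spec) ** 2) / norm
    # one-sided density: double every bin except DC and Nyquist
    psd[..., 1:] *= 2.0
    if nper % 2 == 0:
        psd[..., -1] /= 2.0
    freqs = np.fft.rfftfreq(nper, 1.0 / es.fs)
    return freqs, psd.mean(axis=0)


def relative_band_power(
    freqs: np.ndarray,
    psd: np.ndarray,
    channels: tuple[str, ...],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    subject_id: str = "",
) -> SpectralFeatures:
    """Relative band power in percent of total power over the analysis range.

    Band power sums PSD bins with ``lo <= f < hi``; the top band is closed
    at its upper edge so the analysis range [1, 55] is fully covered with
    no double-counted bin.
    """
    psd = np.asarray(psd)
    top = max(b.hi for b in bands)
    band_powers = {}
    for b in bands:
        mask = (freqs >= b.lo) & ((freqs < b.hi) | ((b.hi == top) & (freqs == top)))
        if not mask.any():
            raise ValueError(f"band {b.name} [{b.lo}, {b.hi}) contains no bins")
        band_powers[b.name] = psd[:, mask].sum(axis=1)
    total = np.sum(list(band_powers.values()), axis=0)
    if np.any(total <= 0):
        raise ValueError("zero total power in analysis range")
    rel = pd.DataFrame(
        {ch: [100.0 * band_powers[b.name][i] / total[i] for b in bands]
         for i, ch in enumerate(channels)},
        index=[b.name for b in bands],
    )
    rel[GLOBAL] = rel.mean(axis=1)
    return SpectralFeatures(subject_id=subject_id, rel_power=rel)


def spectral_feature_row(feat: SpectralFeatures) -> dict[str, float]:
    """Flatten to named features: ``<band>_power_<channel|Global>``."""
    out: dict[str, float] = {}
    for band in feat.rel_power.index:
        for loc in feat.rel_power.columns:
            out[f"{band}_power_{loc}"] = float(feat.rel_power.at[band, loc])
    return out


def compute_spectral_features(
    es: EpochSet, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> SpectralFeatures:
    """Convenience wrapper: Welch PSD then relative band power."""
    freqs, psd = welch_psd(es)
    return relative_band_power(freqs, psd, es.channels, bands, subject_id=es.subject_id)
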