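"""Weighted phase-lag index (wPLI) functional connectivity.

The wPLI weights phase-lead/lag contributions by the magnitude of the
imaginary cross-spectrum, which makes it insensitive to instantaneous
(zero-lag) coupling such as volume conduction:

    wPLI(f) = | E[ Im S_xy(f) ] | / E[ |Im S_xy(f)| ]

with the expectation taken over epochs and 0/0 defined as 0.  The band
value is the unweighted mean of wPLI(f) over the band's frequency bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import DEFAULT_BANDS, BandDefinition, EpochSet

__all__ = ["ConnectivityMatrix", "wpli_matrix", "wpli_matrices"]


@dataclass
class ConnectivityMatrix:
    """Symmetric, zero-diagonal wPLI matrix over the montage channels."""

    subject_id: str
    band: str
    W: np.ndarray
    channels: tuple[str, ...]

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise ValueError("W must be square")
        self.W = W


def _cross_spectra(
    es: EpochSet, bins: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Hamming-tapered epoch FFTs -> imaginary cross-spectra.

    Returns ``(freqs, imag)`` with ``imag`` of shape
    epochs x channels x channels x bins; ``bins`` optionally restricts the
    computation to a boolean frequency-bin mask.
    """
    nper = es.epochs.shape[2]
    window = np.hamming(nper)
    spec = np.fft.rfft(es.epochs * window, axis=2)  # epochs x ch x bins
    freqs = np.fft.rfftfreq(nper, 1.0 / es.fs)
    if bins is not None:
        spec = spec[:, :, bins]
        freqs = freqs[bins]
    # Im(X_i * conj(X_j)) for every pair, per epoch and bin
    imag = np.einsum("eif,ejf->eijf", spec.imag, spec.real) - np.einsum(
        "eif,ejf->eijf", spec.real, spec.imag
    )
    return freqs, imag


def _wpli_from_imag(imag: np.ndarray) -> np.ndarray:
    """wPLI per channel pair and bin from imaginary cross-spectra."""
    num = np.abs(imag.mean(axis=0))
    den = np.abs(imag).mean(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(den > 0, num / den, 0.0)
    return w


def wpli_matrix(es: EpochSet, band: BandDefinition) -> ConnectivityMatrix:
    """Band-averaged wPLI matrix from epoched data.

    Requires at least two epochs (the epoch ensemble is the averaging
    set); the diagonal is zero and values lie in [0, 1].
    """
    if es.n_epochs < 2:
        raise ValueError("wPLI requires at least 2 epochs")
    all_freqs = np.fft.rfftfreq(es.epochs.shape[2], 1.0 / es.fs)
    top = max(b.hi for b in DEFAULT_BANDS)
    mask = (all_freqs >= band.lo) & (
        (all_freqs < band.hi) | ((band.hi == top) & (all_freqs == top))
    )
    freqs, imag = _cross_spectra(es, bins=mask)
    return _band_matrix(es, band, freqs, _wpli_from_imag(imag))


def _band_matrix(
    es: EpochSet, band: BandDefinition, freqs: np.ndarray, w: np.ndarray
) -> ConnectivityMatrix:
    top = max(b.hi for b in DEFAULT_BANDS)
    mask = (freqs >= band.lo) & (
        (freqs < band.hi) | ((band.hi == top) & (freqs == top))
    )
    if not mask.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    W = w[:, :, mask].mean(axis=2)
    np.fill_diagonal(W, 0.0)
    W = 0.5 * (W + W.T)  # exact symmetry despite floating-point noise
    return ConnectivityMatrix(es.subject_id, band.name, W, es.channels)


def wpli_matrices(
    es: EpochSet, bands: tuple[BandDefinition, ...] = DEFAULT_BANDS
) -> dict[str, ConnectivityMatrix]:
    """All band wPLI matrices with the FFT/cross-spectrum computed once."""
    if es.n_epochs < 2:
        raise ValueError("wPLI requires at least 2 epochs")
    all_freqs = np.fft.rfftfreq(es.epochs.shape[2], 1.0 / es.fs)
    lo = min(b.lo for b in bands)
    hi = max(b.hi for b in bands)
    mask = (all_freqs >= lo) & (all_freqs <= hi)
    freqs, imag = _cross_spectra(es, bins=mask)
    w = _wpli_from_imag(imag)
    return {b.name: _band_matrix(es, b, freqs, w) for b in bands}
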