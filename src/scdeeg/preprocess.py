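"""Filtering, epoching, artifact rejection, and epoch selection.

The analysis pipeline band-passes the continuous signal to 1-55 Hz with a
zero-phase filter, cuts non-overlapping 2-s epochs, flags epochs whose
peak-to-peak amplitude exceeds a threshold on any channel, and randomly
retains a fixed number (default 60) of clean epochs per subject.

Artifact handling is a deterministic peak-to-peak amplitude criterion
(default 150 µV).  A ``clean_hook`` argument on :func:`preprocess_recording`
lets callers plug an external cleaning step (e.g. ICA-based) ahead of the
threshold screen.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
from scipy import signal

from .core import EpochSet, Recording

__all__ = [
    "bandpass_filter",
    "segment_epochs",
    "reject_and_select_epochs",
    "preprocess_recording",
    "InsufficientEpochsError",
]


class InsufficientEpochsError(RuntimeError):
    """Raised when a subject has fewer clean epochs than requested."""


def bandpass_filter(rec: Recording, lo: float = 1.0, hi: float = 55.0) -> Recording:
    """Zero-phase Butterworth band-pass (4th order per pass, forward-backward).

    Zero-phase filtering avoids phase distortion that would bias
    phase-based connectivity estimates downstream.
    """
    nyq = rec.fs / 2.0
    if not (0 < lo < hi):
        raise ValueError(f"need 0 < lo < hi, got lo={lo}, hi={hi}")
    if hi >= nyq:
        raise ValueError(f"high cutoff {hi} Hz >= Nyquist {nyq} Hz")
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rec.fs, output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    return Recording(rec.subject_id, filtered, rec.fs, rec.channels)


def segment_epochs(rec: Recording, epoch_length: float = 2.0) -> EpochSet:
    """Cut consecutive non-overlapping epochs; drop the trailing partial one."""
    spe = int(round(epoch_length * rec.fs))
    n_epochs = rec.n_samples // spe
    if n_epochs < 1:
        raise ValueError(
            f"recording {rec.subject_id}: duration {rec.duration:.2f} s shorter "
            f"than one {epoch_length} s epoch"
        )
    trimmed = rec.data[:, : n_epochs * spe]
    epochs = trimmed.reshape(rec.n_channels, n_epochs, spe).transpose(1, 0, 2)
    return EpochSet(
        subject_id=rec.subject_id,
        epochs=epochs.copy(),
        fs=rec.fs,
        epoch_length=epoch_length,
        channels=rec.channels,
        selected_indices=np.arange(n_epochs),
    )


def flag_artifact_epochs(es: EpochSet, amp_thresh_uV: float = 150.0) -> np.ndarray:
    """Boolean mask of epochs whose peak-to-peak exceeds the threshold on any channel."""
    ptp = es.epochs.max(axis=2) - es.epochs.min(axis=2)  # epochs x channels
    return (ptp > amp_thresh_uV).any(axis=1)


def reject_and_select_epochs(
    es: EpochSet,
    amp_thresh_uV: float = 150.0,
    n_select: int = 60,
    seed: int = 0,
) -> EpochSet:
    """Reject high-amplitude epochs, then randomly retain ``n_select`` clean ones.

    Selection is uniform without replacement, deterministic given ``seed``;
    the retained epochs keep their original temporal order and their
    original indices are recorded in ``selected_indices``.
    """
    if es.n_epochs == 0:
        raise ValueError("empty epoch set")
    flagged = flag_artifact_epochs(es, amp_thresh_uV)
    clean = np.flatnonzero(~flagged)
    if clean.size < n_select:
        raise InsufficientEpochsError(
            f"subject {es.subject_id}: only {clean.size} clean epochs "
            f"(< {n_select} requested) at threshold {amp_thresh_uV} µV"
        )
    rng = np.random.default_rng(seed)
    chosen = np.sort(rng.choice(clean, size=n_select, replace=False))
    original = es.selected_indices[chosen] if es.selected_indices.size else chosen
    return EpochSet(
        subject_id=es.subject_id,
        epochs=es.epochs[chosen],
        fs=es.fs,
        epoch_length=es.epoch_length,
        channels=es.channels,
        selected_indices=original,
    )


def preprocess_recording(
    rec: Recording,
    lo: float = 1.0,
    hi: float = 55.0,
    epoch_length: float = 2.0,
    amp_thresh_uV: float = 150.0,
    n_select: int = 60,
    seed: int = 0,
    clean_hook: Callable[[Recording], Recording] | None = None,
) -> EpochSet:
    """Full preprocessing chain: (hook) -> band-pass -> epoch -> reject/select."""
    if clean_hook is not None:
        rec = clean_hook(rec)
    rec = bandpass_filter(rec, lo, hi)
    es = segment_epochs(rec, epoch_length)
    return reject_and_select_epochs(es, amp_thresh_uV, n_select, seed)
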