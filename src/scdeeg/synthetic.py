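"""Synthetic two-group EEG cohort generator.

Emulates the statistical structure of a prospective subjective-cognitive-
decline (SCD) cohort split by amyloid-PET status: a small amyloid-positive
(A+) group (default n=24) against a larger amyloid-negative (A-) group
(default n=82), with planted group effects in the directions reported for
such cohorts:

* elevated low-frequency (delta/theta) and reduced alpha relative power
  in A+;
* reduced alpha-band lagged phase coupling (hence lower alpha clustering
  coefficient / node strength) and mildly elevated delta coupling in A+;
* an age offset between groups, APOE4 carrier rates near 50% vs 11%;
* cognitive percentile scores driven by a latent severity variable that
  also scales the subject's EEG profile, planting negative theta-score
  and positive alpha-score correlations.

Signals are sums of band-limited Gaussian noise sources (some shared
across channel groups with per-channel integer-sample lags), a 1/f-shaped
background, and white sensor noise.  Everything is a pure function of
(spec, seed); per-subject child seeds are derived with a counter-based
scheme so cohorts reproduce independently of generation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .core import BAND_NAMES, CHANNELS_1020, Recording, band_by_name

__all__ = [
    "SubjectMeta",
    "CouplingSpec",
    "CohortSpec",
    "generate_subject_recording",
    "generate_cohort",
    "inject_artifacts",
    "generate_covariates_and_scores",
    "child_seed",
]

GROUPS = ("A_plus", "A_minus")

#: Default cognitive test score columns (percentile scores, 0-100).
DEFAULT_SCORE_NAMES = ("K_MMSE", "SVLT", "DSC", "K_TMT_B")


@dataclass
class SubjectMeta:
    subject_id: str
    group: str                       # "A_plus" or "A_minus"
    age: float = 70.0
    sex: str = "female"              # "male" / "female"
    education: float = 12.0
    apoe4: bool = False
    cognitive_scores: dict[str, float] = field(default_factory=dict)
    severity: float = 0.0            # latent disease burden (synthetic only)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.age <= 0:
            raise ValueError("age must be positive")
        for k, v in self.cognitive_scores.items():
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"cognitive score {k}={v} outside [0, 100]")


@dataclass(frozen=True)
class CouplingSpec:
    """A shared narrowband source injected into a channel set with lags.

    The first channel receives the source with zero lag; channel ``j`` of
    the set receives it delayed by ``j * lag_ms``.  ``strength`` in [0, 1]
    is the mixing proportion of the shared source in each channel's band
    signal (RMS-preserving mixing).
    """

    channels: tuple[str, ...]
    band: str
    lag_ms: float
    strength: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.strength <= 1.0):
            raise ValueError("coupling strength must be in [0, 1]")
        if self.lag_ms < 0:
            raise ValueError("lag_ms must be >= 0")
        band_by_name(self.band)  # raises on unknown band
        for ch in self.channels:
            if ch not in CHANNELS_1020:
                raise ValueError(f"unknown channel in coupling spec: {ch!r}")


def _default_profiles() -> dict[str, dict[str, float]]:
    # Baseline per-band source RMS amplitudes (µV); together with the 1/f
    # background these give an eyes-closed-like relative power profile
    # (alpha-dominant, delta ~20-25%).  A+ multipliers plant the
    # delta/theta-up, alpha-down pattern; magnitudes chosen so ANCOVA
    # partial eta^2 on relative power lands in the 0.04-0.10 range at
    # n = 24 + 82.
    base = {"delta": 3.7, "theta": 3.0, "alpha": 6.1, "beta": 3.6, "gamma": 0.9}
    pos = dict(base)
    pos["delta"] *= 1.08
    pos["theta"] *= 1.06
    pos["alpha"] *= 0.93
    return {"A_plus": pos, "A_minus": base}


def _default_coupling() -> dict[str, tuple[CouplingSpec, ...]]:
    posterior = ("T5", "P3", "Pz", "P4", "T6", "O1", "O2")
    frontal = ("Fp1", "F7", "F3", "Fz", "F4")
    return {
        "A_plus": (
            CouplingSpec(posterior, "alpha", lag_ms=10.0, strength=0.38),
            CouplingSpec(frontal, "delta", lag_ms=15.0, strength=0.32),
        ),
        "A_minus": (
            CouplingSpec(posterior, "alpha", lag_ms=10.0, strength=0.52),
            CouplingSpec(frontal, "delta", lag_ms=15.0, strength=0.22),
        ),
    }


@dataclass
class CohortSpec:
    """Parameters of the synthetic cohort; defaults emulate the study cohort."""

    n_pos: int = 24
    n_neg: int = 82
    fs: float = 250.0
    duration: float = 180.0
    band_amplitude_profiles: dict[str, dict[str, float]] = field(
        default_factory=_default_profiles
    )
    coupling_spec: dict[str, tuple[CouplingSpec, ...]] = field(
        default_factory=_default_coupling
    )
    background_rms: float = 5.0        # 1/f background amplitude, µV RMS
    sensor_noise_rms: float = 1.0      # white noise floor, µV RMS
    amplitude_jitter_sd: float = 0.30  # lognormal sd of per-subject band RMS
    coupling_jitter_sd: float = 0.15   # per-subject sd of coupling strengths
    severity_gain: float = 0.15        # per-unit-severity log-scaling of bands
    age_means: dict[str, float] = field(
        default_factory=lambda: {"A_plus": 73.42, "A_minus": 69.82}
    )
    age_sds: dict[str, float] = field(
        default_factory=lambda: {"A_plus": 5.64, "A_minus": 6.05}
    )
    apoe4_rates: dict[str, float] = field(
        default_factory=lambda: {"A_plus": 0.50, "A_minus": 0.11}
    )
    male_rates: dict[str, float] = field(
        default_factory=lambda: {"A_plus": 0.583, "A_minus": 0.390}
    )
    education_means: dict[str, float] = field(
        default_factory=lambda: {"A_plus": 12.71, "A_minus": 11.04}
    )
    education_sds: dict[str, float] = field(
        default_factory=lambda: {"A_plus": 4.07, "A_minus": 3.88}
    )
    severity_means: dict[str, float] = field(
        default_factory=lambda: {"A_plus": 1.0, "A_minus": 0.0}
    )
    severity_sd: float = 0.8
    score_names: tuple[str, ...] = DEFAULT_SCORE_NAMES
    score_baseline: float = 65.0       # percentile level at severity 0
    score_slope: float = 12.0          # percentile loss per unit severity
    score_noise_sd: float = 9.0
    artifact_rate: float = 2.0         # transient events per minute
    artifact_amplitude: float = 400.0  # µV
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pos < 2 or self.n_neg < 2:
            raise ValueError("n_pos and n_neg must both be >= 2")
        if self.duration <= 0 or self.fs <= 0:
            raise ValueError("fs and duration must be positive")
        for group, profile in self.band_amplitude_profiles.items():
            for band in profile:
                if band not in BAND_NAMES:
                    raise ValueError(
                        f"unknown band {band!r} in amplitude profile for {group}"
                    )


def child_seed(master_seed: int, *keys: int) -> int:
    """Derive a reproducible child seed from a master seed and counters."""
    ss = np.random.SeedSequence([int(master_seed), *map(int, keys)])
    return int(ss.generate_state(1, dtype=np.uint32)[0]) % (2**31)


# ---------------------------------------------------------------------------
# signal synthesis (frequency-domain construction for speed)
# ---------------------------------------------------------------------------

def _band_mask(freqs: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return (freqs >= lo) & (freqs < hi)


def _compact_spectrum(
    rng: np.random.Generator,
    n_rows: int,
    k: int,
    n: int,
    shaping: np.ndarray | None = None,
) -> np.ndarray:
    """Unit-RMS complex spectra on ``k`` active bins (compact n_rows x k).

    RMS normalization uses Parseval's identity (DC/Nyquist are never
    among the active bins), so no round trip to the time domain is needed.
    """
    if k == 0:
        raise ValueError("frequency mask contains no bins")
    noise = rng.standard_normal((n_rows, k)) + 1j * rng.standard_normal((n_rows, k))
    if shaping is not None:
        noise = noise * shaping
    # sum x^2 = (2/n) * sum |X_k|^2 for one-sided bins excluding DC/Nyquist
    rms = np.sqrt(2.0 * np.sum(np.abs(noise) ** 2, axis=1) / n**2)
    return noise / np.maximum(rms, 1e-30)[:, None]


def _narrowband_source(
    rng: np.random.Generator, n: int, fs: float, lo: float, hi: float,
    shape: tuple[int, ...] = (),
) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi) (time domain)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = _band_mask(freqs, lo, hi)
    n_rows = int(np.prod(shape)) if shape else 1
    spec = np.zeros((n_rows, freqs.size), dtype=complex)
    spec[:, mask] = _compact_spectrum(rng, n_rows, int(mask.sum()), n)
    x = np.fft.irfft(spec, n=n, axis=-1)
    return x.reshape(shape + (n,)) if shape else x[0]


#: Background spectral support: a 1/f slope over this range keeps the
#: analysis band (1-55 Hz) fully covered without injecting large
#: sub-band power that would leak into the delta estimates.
_BG_LO, _BG_HI = 0.75, 60.0


def _pink_background(
    rng: np.random.Generator, n: int, fs: float, n_channels: int
) -> np.ndarray:
    """Unit-RMS 1/f background (PSD slope -1 over the analysis range)."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= _BG_LO) & (freqs <= _BG_HI)
    spec = np.zeros((n_channels, freqs.size), dtype=complex)
    spec[:, mask] = _compact_spectrum(
        rng, n_channels, int(mask.sum()), n, shaping=freqs[mask] ** -0.5
    )
    return np.fft.irfft(spec, n=n, axis=-1)


def _severity_factor(band: str, severity: float, gain: float) -> float:
    """Severity scales delta/theta up and alpha down, multiplicatively."""
    if band in ("delta", "theta"):
        return float(np.exp(gain * severity))
    if band == "alpha":
        return float(np.exp(-gain * severity))
    return 1.0


def generate_subject_recording(
    spec: CohortSpec, meta: SubjectMeta, seed: int
) -> Recording:
    """Synthesize one subject's 19-channel recording.

    The signal is the sum over bands of amplitude-scaled narrowband
    sources (mixed with shared lagged sources per the group's coupling
    spec), a 1/f background, and a white sensor-noise floor.  Deterministic
    given (spec, meta, seed).
    """
    rng = np.random.default_rng(seed)
    n = int(round(spec.duration * spec.fs))
    n_ch = len(CHANNELS_1020)
    ch_index = {c: i for i, c in enumerate(CHANNELS_1020)}
    profile = spec.band_amplitude_profiles[meta.group]
    couplings = spec.coupling_spec.get(meta.group, ())
    freqs = np.fft.rfftfreq(n, 1.0 / spec.fs)

    # The whole multi-source signal is assembled as one rfft spectrum per
    # channel (narrowband sources, lags as phase ramps, 1/f background),
    # then inverted once; circular delays are exact for stationary noise.
    total = np.zeros((n_ch, freqs.size), dtype=complex)

    bg_mask = (freqs >= _BG_LO) & (freqs <= _BG_HI)
    total[:, bg_mask] += spec.background_rms * _compact_spectrum(
        rng, n_ch, int(bg_mask.sum()), n, shaping=freqs[bg_mask] ** -0.5
    )

    # per-subject multiplicative amplitude jitter, one factor per band
    jitter = np.exp(spec.amplitude_jitter_sd * rng.standard_normal(len(BAND_NAMES)))

    for bi, band_name in enumerate(BAND_NAMES):
        band = band_by_name(band_name)
        amp = (
            profile.get(band_name, 0.0)
            * jitter[bi]
            * _severity_factor(band_name, meta.severity, spec.severity_gain)
        )
        if amp <= 0:
            continue
        mask = _band_mask(freqs, band.lo, band.hi)
        k = int(mask.sum())
        own = _compact_spectrum(rng, n_ch, k, n)
        # mixing proportions of the shared source, per channel
        g = np.zeros(n_ch)
        shared = np.zeros((n_ch, k), dtype=complex)
        fband = freqs[mask]
        for cpl in couplings:
            if cpl.band != band_name or cpl.strength == 0.0:
                continue
            s = _compact_spectrum(rng, 1, k, n)[0]
            lag = int(round(cpl.lag_ms * 1e-3 * spec.fs))
            # per-subject coupling-strength variability
            strength = float(np.clip(
                cpl.strength + spec.coupling_jitter_sd * rng.standard_normal(),
                0.0, 0.95,
            ))
            for j, ch in enumerate(cpl.channels):
                i = ch_index[ch]
                # delay by j*lag samples == phase ramp in the spectrum
                shared[i] = s * np.exp(-2j * np.pi * fband * (j * lag) / spec.fs)
                g[i] = strength
        # RMS-preserving mix of independent own and shared sources
        total[:, mask] += amp * (
            np.sqrt(1.0 - g[:, None] ** 2) * own + g[:, None] * shared
        )

    data = np.fft.irfft(total, n=n, axis=-1)
    data += spec.sensor_noise_rms * rng.standard_normal((n_ch, n))
    return Recording(meta.subject_id, data, spec.fs, CHANNELS_1020)


def inject_artifacts(
    rec: Recording, rate_per_min: float, amplitude_uV: float, seed: int
) -> Recording:
    """Add brief high-amplitude transients at Poisson-distributed times.

    Returns a modified copy; the event log (list of dicts with onset
    seconds, channel index, and duration) is attached as
    ``Recording.artifact_log``.
    """
    if rate_per_min < 0:
        raise ValueError("rate_per_min must be >= 0")
    if amplitude_uV <= 0:
        raise ValueError("artifact amplitude must be positive")
    out = rec.copy()
    out.artifact_log = []  # type: ignore[attr-defined]
    if rate_per_min == 0:
        return out
    rng = np.random.default_rng(seed)
    n_events = rng.poisson(rate_per_min * rec.duration / 60.0)
    for _ in range(n_events):
        onset = rng.uniform(0.0, rec.duration - 0.5)
        dur = rng.uniform(0.1, 0.5)
        ch = int(rng.integers(0, rec.n_channels))
        i0 = int(onset * rec.fs)
        width = max(int(dur * rec.fs), 2)
        i1 = min(i0 + width, rec.n_samples)
        bump = amplitude_uV * np.hanning(width)[: i1 - i0]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out.data[ch, i0:i1] += sign * bump
        out.artifact_log.append(  # type: ignore[attr-defined]
            {"onset_s": float(onset), "channel": ch, "duration_s": float(dur)}
        )
    return out


def generate_covariates_and_scores(
    meta: SubjectMeta, spec: CohortSpec, seed: int
) -> SubjectMeta:
    """Fill cognitive percentile scores from the latent severity.

    score = baseline - slope * severity + noise, clipped to [0, 100]; the
    same severity scales the subject's EEG band profile, so negative
    theta-score and positive alpha-score correlations are planted by
    construction.
    """
    rng = np.random.default_rng(seed)
    scores = {}
    for name in spec.score_names:
        raw = (
            spec.score_baseline
            - spec.score_slope * meta.severity
            + spec.score_noise_sd * rng.standard_normal()
        )
        scores[name] = float(np.clip(raw, 0.0, 100.0))
    return replace(meta, cognitive_scores=scores)


def generate_cohort(spec: CohortSpec) -> list[tuple[Recording, SubjectMeta]]:
    """Generate the full two-group cohort, A+ subjects first.

    Ages are drawn from group-specific normals (floored at 55), APOE4
    carrier status from group-specific Bernoulli rates, and each subject's
    recording from a child seed derived from ``spec.seed`` and the subject
    counter, so any subject reproduces independently of the others.
    """
    if spec.n_pos < 2 or spec.n_neg < 2:
        raise ValueError("need at least 2 subjects per group")
    cohort: list[tuple[Recording, SubjectMeta]] = []
    counter = 0
    for group, n_group in (("A_plus", spec.n_pos), ("A_minus", spec.n_neg)):
        for _ in range(n_group):
            meta_rng = np.random.default_rng(child_seed(spec.seed, counter, 0))
            age = max(
                55.0,
                spec.age_means[group] + spec.age_sds[group] * meta_rng.standard_normal(),
            )
            sex = "male" if meta_rng.random() < spec.male_rates[group] else "female"
            education = float(
                np.clip(
                    spec.education_means[group]
                    + spec.education_sds[group] * meta_rng.standard_normal(),
                    0.0,
                    25.0,
                )
            )
            apoe4 = bool(meta_rng.random() < spec.apoe4_rates[group])
            severity = (
                spec.severity_means[group]
                + spec.severity_sd * meta_rng.standard_normal()
            )
            tag = "pos" if group == "A_plus" else "neg"
            meta = SubjectMeta(
                subject_id=f"sub-{tag}-{counter:03d}",
                group=group,
                age=float(age),
                sex=sex,
                education=education,
                apoe4=apoe4,
                severity=float(severity),
            )
            meta = generate_covariates_and_scores(
                meta, spec, child_seed(spec.seed, counter, 1)
            )
            rec = generate_subject_recording(
                spec, meta, child_seed(spec.seed, counter, 2)
            )
            if spec.artifact_rate > 0:
                rec = inject_artifacts(
                    rec,
                    spec.artifact_rate,
                    spec.artifact_amplitude,
                    child_seed(spec.seed, counter, 3),
                )
            cohort.append((rec, meta))
            counter += 1
    return cohort
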