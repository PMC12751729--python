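"""Group-comparison and association statistics.

Conventions follow common clinical-EEG reporting practice:

* normality screened by sample skewness (|skew| < 2) and excess kurtosis
  (|kurtosis| < 7) rather than formal tests;
* independent two-group comparisons use the pooled-variance t-test with
  pooled-SD Cohen's d (positive when the larger, amyloid-negative group
  mean exceeds the amyloid-positive group mean) and the usual large-sample
  95% CI  d ± 1.96·sqrt((n1+n2)/(n1·n2) + d²/(2(n1+n2)));
* categorical contrasts use the Pearson chi-square without continuity
  correction;
* EEG feature contrasts use ANCOVA with a covariate (age by default) and
  partial eta squared = SS_group / (SS_group + SS_residual);
* EEG-cognition associations use age-adjusted partial correlations with a
  percentile bootstrap CI (default 5,000 resamples).

No multiple-comparison correction is applied by default; a
Benjamini-Hochberg FDR helper is provided as an opt-in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "GroupComparisonResult",
    "PartialCorrelationResult",
    "normality_check",
    "independent_t_and_d",
    "paired_t_and_d",
    "chi_square_test",
    "ancova_partial_eta2",
    "partial_correlation_bootstrap",
    "fdr_bh",
]


@dataclass
class GroupComparisonResult:
    statistic: float
    p_value: float
    effect_size: float
    effect_type: str                       # "cohens_d" | "partial_eta_squared" | "none"
    ci95: tuple[float, float] | None = None
    n1: int = 0
    n2: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value {self.p_value} outside [0, 1]")
        if self.effect_type == "partial_eta_squared" and not (
            0.0 <= self.effect_size <= 1.0
        ):
            raise ValueError("partial eta squared must lie in [0, 1]")


@dataclass
class PartialCorrelationResult:
    r: float
    p_value: float
    ci95: tuple[float, float]
    n: int
    n_boot: int


def normality_check(x: np.ndarray) -> bool:
    """Moment-based normality screen: |skewness| < 2 and |excess kurtosis| < 7."""
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.var(x) == 0:
        raise ValueError("zero-variance sample")
    skew = sps.skew(x)
    kurt = sps.kurtosis(x)  # Fisher (excess) kurtosis
    return bool(abs(skew) < 2.0 and abs(kurt) < 7.0)


def _d_ci(d: float, n1: int, n2: int) -> tuple[float, float]:
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * (n1 + n2)))
    return (d - 1.96 * se, d + 1.96 * se)


def cohens_d_from_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> float:
    """Pooled-SD Cohen's d, positive when group 2's mean exceeds group 1's."""
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    s_pooled = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / (n1 + n2 - 2))
    if s_pooled == 0:
        raise ValueError("zero pooled variance")
    return float((mean2 - mean1) / s_pooled)


def independent_t_and_d(
    x1: np.ndarray | tuple[float, float, int],
    x2: np.ndarray | tuple[float, float, int],
) -> GroupComparisonResult:
    """Pooled-variance two-sided t-test with Cohen's d and its 95% CI.

    Each argument is either a raw sample or a ``(mean, sd, n)`` summary
    triple; d is positive when the second group's mean is larger (the
    study's A- minus A+ orientation with A+ passed first).
    """
    def summarize(x):
        if isinstance(x, tuple) and len(x) == 3:
            return float(x[0]), float(x[1]), int(x[2])
        arr = np.asarray(x, dtype=float)
        return float(arr.mean()), float(arr.std(ddof=1)), int(arr.size)

    m1, s1, n1 = summarize(x1)
    m2, s2, n2 = summarize(x2)
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    d = cohens_d_from_summary(m1, s1, n1, m2, s2, n2)
    sp2 = ((n1 - 1) * s1**2 + (n2 - 1) * s2**2) / (n1 + n2 - 2)
    t = (m1 - m2) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    df = n1 + n2 - 2
    p = 2 * sps.t.sf(abs(t), df)
    return GroupComparisonResult(
        statistic=float(t),
        p_value=float(p),
        effect_size=d,
        effect_type="cohens_d",
        ci95=_d_ci(d, n1, n2),
        n1=n1,
        n2=n2,
    )


def paired_t_and_d(x_pre: np.ndarray, x_post: np.ndarray) -> GroupComparisonResult:
    """Paired two-sided t-test on pre - post differences.

    d = mean(diff) / sd(diff): negative when follow-up scores exceed
    baseline (improvement).
    """
    x_pre = np.asarray(x_pre, dtype=float)
    x_post = np.asarray(x_post, dtype=float)
    if x_pre.shape != x_post.shape:
        raise ValueError("paired samples must have equal length")
    n = x_pre.size
    if n < 2:
        raise ValueError("need n >= 2 pairs")
    diff = x_pre - x_post
    sd = diff.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences")
    d = float(diff.mean() / sd)
    t = diff.mean() / (sd / np.sqrt(n))
    p = 2 * sps.t.sf(abs(t), n - 1)
    return GroupComparisonResult(
        statistic=float(t), p_value=float(p), effect_size=d,
        effect_type="cohens_d", n1=n, n2=n,
    )


def chi_square_test(table: np.ndarray) -> GroupComparisonResult:
    """Pearson chi-square on a 2x2 count table, no continuity correction."""
    table = np.asarray(table, dtype=float)
    if table.shape != (2, 2):
        raise ValueError("expected a 2x2 count table")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero marginal in contingency table")
    chi2, p, dof, expected = sps.chi2_contingency(table, correction=False)
    if np.any(expected <= 0):
        raise ValueError("expected counts must be positive")
    return GroupComparisonResult(
        statistic=float(chi2), p_value=float(p), effect_size=float("nan"),
        effect_type="none", n1=int(table[0].sum()), n2=int(table[1].sum()),
    )


def ancova_partial_eta2(
    y: np.ndarray, group: np.ndarray, covariate: np.ndarray
) -> GroupComparisonResult:
    """ANCOVA: y ~ intercept + group + covariate; F for group, partial eta^2.

    partial eta^2 = SS_group / (SS_group + SS_residual), where SS_group is
    the reduction in residual SS from adding the group indicator to the
    covariate-only model.
    """
    y = np.asarray(y, dtype=float)
    group = np.asarray(group)
    cov = np.asarray(covariate, dtype=float)
    n = y.size
    if n < 4:
        raise ValueError("need at least 4 observations")
    levels = np.unique(group)
    if levels.size != 2:
        raise ValueError(f"expected exactly 2 groups, got {levels.size}")
    g = (group == levels[1]).astype(float)
    X_full = np.column_stack([np.ones(n), g, cov])
    X_red = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(X_full) < 3:
        raise ValueError("covariate collinear with group indicator")
    beta_f, *_ = np.linalg.lstsq(X_full, y, rcond=None)
    beta_r, *_ = np.linalg.lstsq(X_red, y, rcond=None)
    sse_full = float(np.sum((y - X_full @ beta_f) ** 2))
    sse_red = float(np.sum((y - X_red @ beta_r) ** 2))
    ss_group = max(sse_red - sse_full, 0.0)
    df_resid = n - 3
    F = (ss_group / 1.0) / (sse_full / df_resid) if sse_full > 0 else np.inf
    p = float(sps.f.sf(F, 1, df_resid)) if np.isfinite(F) else 0.0
    eta2 = ss_group / (ss_group + sse_full) if (ss_group + sse_full) > 0 else 0.0
    n1 = int(np.sum(group == levels[0]))
    return GroupComparisonResult(
        statistic=float(F), p_value=p, effect_size=float(eta2),
        effect_type="partial_eta_squared", n1=n1, n2=n - n1,
    )


def _residualize(v: np.ndarray, cov: np.ndarray) -> np.ndarray:
    X = np.column_stack([np.ones(v.size), cov])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta


def partial_correlation_bootstrap(
    x: np.ndarray,
    y: np.ndarray,
    covariate: np.ndarray,
    n_boot: int = 5000,
    seed: int = 0,
) -> PartialCorrelationResult:
    """Covariate-adjusted Pearson correlation with a percentile bootstrap CI.

    r is the correlation of the least-squares residuals of x and y on the
    covariate; the p-value uses t = r sqrt((n-3)/(1-r^2)) on n-3 df; the
    95% CI is the percentile interval over ``n_boot`` subject-level
    resamples (deterministic given ``seed``).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = np.asarray(covariate, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    rx = _residualize(x, cov)
    ry = _residualize(y, cov)
    if rx.std() == 0 or ry.std() == 0:
        raise ValueError("constant residuals after covariate adjustment")
    r = float(np.corrcoef(rx, ry)[0, 1])
    r = float(np.clip(r, -1.0, 1.0))
    if abs(r) < 1.0:
        t = r * np.sqrt((n - 3) / (1 - r**2))
        p = float(2 * sps.t.sf(abs(t), n - 3))
    else:
        p = 0.0

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    xb, yb, cb = x[idx], y[idx], cov[idx]
    # closed-form single-covariate residualization, vectorized over resamples
    cbc = cb - cb.mean(axis=1, keepdims=True)
    denom = np.maximum((cbc**2).sum(axis=1), 1e-30)

    def resid(v):
        vc = v - v.mean(axis=1, keepdims=True)
        beta = (vc * cbc).sum(axis=1) / denom
        return vc - beta[:, None] * cbc

    rxb, ryb = resid(xb), resid(yb)
    num = (rxb * ryb).sum(axis=1)
    den = np.sqrt((rxb**2).sum(axis=1) * (ryb**2).sum(axis=1))
    rb = num / np.maximum(den, 1e-30)
    lo, hi = np.percentile(rb, [2.5, 97.5])
    return PartialCorrelationResult(
        r=r, p_value=p, ci95=(float(lo), float(hi)), n=n, n_boot=n_boot
    )


def fdr_bh(p_values: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg rejection mask (opt-in; analyses default to none)."""
    from statsmodels.stats.multitest import multipletests

    reject, *_ = multipletests(np.asarray(p_values, float), alpha=alpha, method="fdr_bh")
    return reject
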