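"""Imbalance-aware, interpretable classification of amyloid status.

Feature assembly (EEG spectral + network features + age, or a demographic/
cognitive set), greedy sequential forward selection (<= 20 features) under
a boosted-stump classifier, stratified 10-fold cross-validation with
Borderline-SMOTE oversampling applied to training folds only, standard
confusion-matrix metrics, label-permutation significance testing, and exact
Shapley attribution of the fitted ensemble.

The positive class is A+ (amyloid-positive) throughout: sensitivity is the
A+ detection rate, and positive Shapley values push predictions toward A+.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import NearestNeighbors

from .boost import StumpBoost
from .core import BAND_NAMES, CHANNELS_1020

__all__ = [
    "FeatureTable",
    "CVResult",
    "ShapSummary",
    "build_feature_table",
    "borderline_smote",
    "classification_metrics",
    "sfs_select",
    "cv_evaluate",
    "permutation_pvalue",
    "shap_summary",
    "eeg_feature_names",
]

METRIC_NAMES = ("accuracy", "sensitivity", "specificity", "mcc", "f1")

LOCATIONS = CHANNELS_1020 + ("Global",)


def eeg_feature_names(include_age: bool = True) -> list[str]:
    """The documented EEG feature order: power, CC, NS blocks then E, then age."""
    names: list[str] = []
    for band in BAND_NAMES:
        names += [f"{band}_power_{loc}" for loc in LOCATIONS]
    for band in BAND_NAMES:
        names += [f"{band}_CC_{loc}" for loc in LOCATIONS]
    for band in BAND_NAMES:
        names += [f"{band}_NS_{loc}" for loc in LOCATIONS]
    names += [f"{band}_E" for band in BAND_NAMES]
    if include_age:
        names.append("age")
    return names


@dataclass
class FeatureTable:
    """Subjects x features matrix with binary labels (A+ = 1)."""

    subjects: list[str]
    feature_names: list[str]
    X: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.shape != (len(self.subjects), len(self.feature_names)):
            raise ValueError("X shape does not match subjects x feature_names")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature table contains missing/non-finite values")

    def subset(self, features: list[str]) -> "FeatureTable":
        idx = [self.feature_names.index(f) for f in features]
        return FeatureTable(self.subjects, list(features), self.X[:, idx], self.y)


def build_feature_table(
    spectral: pd.DataFrame,
    network: pd.DataFrame,
    meta: pd.DataFrame,
    mode: str = "eeg",
) -> FeatureTable:
    """Assemble the classification table from per-subject feature frames.

    ``spectral`` and ``network`` are indexed by subject_id with the named
    feature columns produced by the spectral/network modules; ``meta`` is
    indexed by subject_id with at least ``group`` and ``age`` (plus sex,
    education_years, apoe4 and cognitive score columns for demographic
    mode).  EEG mode yields 305 EEG features + age = 306 columns.
    """
    subjects = list(meta.index)
    y = (meta["group"] == "A_plus").astype(int).to_numpy()
    if mode == "eeg":
        names = eeg_feature_names(include_age=True)
        joined = spectral.join(network, how="inner")
        missing_subj = set(subjects) - set(joined.index)
        if missing_subj:
            raise KeyError(f"subjects missing from EEG feature frames: {sorted(missing_subj)[:5]}")
        missing_cols = [n for n in names if n != "age" and n not in joined.columns]
        if missing_cols:
            raise KeyError(f"missing EEG feature columns: {missing_cols[:5]}")
        joined = joined.loc[subjects]
        X = joined[[n for n in names if n != "age"]].to_numpy(dtype=float)
        X = np.column_stack([X, meta["age"].to_numpy(dtype=float)])
    elif mode == "demographic":
        cols = ["age", "education_years"]
        frame = meta.copy()
        frame["sex_male"] = (frame["sex"] == "male").astype(float)
        cols.append("sex_male")
        if "apoe4" in frame.columns:
            cols.append("apoe4")
        skip = {"group", "age", "sex", "sex_male", "education_years", "apoe4",
                "severity", "subject_id"}
        extra = [c for c in frame.columns
                 if c not in skip and pd.api.types.is_numeric_dtype(frame[c])]
        names = cols + extra
        X = frame[names].to_numpy(dtype=float)
    else:
        raise ValueError(f"unknown mode {mode!r} (expected 'eeg' or 'demographic')")
    if np.isnan(X).any():
        raise KeyError("missing values after feature join")
    return FeatureTable(subjects, list(names), X, y)


# ---------------------------------------------------------------------------
# scaling and oversampling
# ---------------------------------------------------------------------------

def _zscore_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    if np.any(sd < 1e-12):
        warnings.warn("constant feature column(s) under z-scoring; mapped to zero")
    return mu, np.maximum(sd, 1e-12)


def _zscore_apply(X: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    return (X - mu) / sd


def borderline_smote(
    X: np.ndarray, y: np.ndarray, k_neighbors: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Borderline-SMOTE (variant 1) oversampling of the minority class.

    Minority points whose ``k_neighbors`` nearest neighbors (over all
    samples) include at least k/2 but fewer than k majority points form the
    "danger" set; synthetic points are convex combinations between danger
    points and their nearest minority-class neighbors, raising the minority
    count to the majority count.  Deterministic given ``seed``.  If no
    danger points exist (all minority points are safe or noise), no
    synthesis occurs and a warning is emitted.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts[0] == counts[1]:
        return X.copy(), y.copy()
    minority = int(np.argmin(counts))
    n_min, n_maj = counts[minority], counts.max()
    if n_min < k_neighbors + 1:
        raise ValueError(
            f"minority class has {n_min} members; Borderline-SMOTE with "
            f"k={k_neighbors} needs at least {k_neighbors + 1}"
        )
    min_idx = np.flatnonzero(y == minority)
    Xmin = X[min_idx]

    nn_all = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(X)
    _, nbrs = nn_all.kneighbors(Xmin)
    nbrs = nbrs[:, 1:]  # drop self
    n_majority_nbrs = (y[nbrs] != minority).sum(axis=1)
    half = k_neighbors / 2.0
    danger = (n_majority_nbrs >= half) & (n_majority_nbrs < k_neighbors)
    if not danger.any():
        warnings.warn("Borderline-SMOTE: empty danger set, no synthetic samples")
        return X.copy(), y.copy()

    danger_pts = Xmin[danger]
    k_syn = min(k_neighbors, n_min - 1)
    nn_min = NearestNeighbors(n_neighbors=k_syn + 1).fit(Xmin)
    _, min_nbrs = nn_min.kneighbors(danger_pts)
    min_nbrs = min_nbrs[:, 1:]

    rng = np.random.default_rng(seed)
    n_new = int(n_maj - n_min)
    base = rng.integers(0, danger_pts.shape[0], size=n_new)
    pick = rng.integers(0, k_syn, size=n_new)
    gaps = rng.random(n_new)
    partners = Xmin[min_nbrs[base, pick]]
    synthetic = danger_pts[base] + gaps[:, None] * (partners - danger_pts[base])
    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority)])
    return X_out, y_out


# ---------------------------------------------------------------------------
# metrics
# ---------------------------------------------------------------------------

def classification_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """Accuracy, sensitivity, specificity, MCC and F1 from confusion counts.

    Undefined ratios (empty denominator) are NaN except MCC, which is 0 by
    convention when any marginal is empty.
    """
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("empty confusion matrix")
    acc = (tp + tn) / total
    sens = tp / (tp + fn) if (tp + fn) > 0 else float("nan")
    spec = tn / (tn + fp) if (tn + fp) > 0 else float("nan")
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else float("nan")
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / np.sqrt(denom) if denom > 0 else 0.0
    return {"accuracy": acc, "sensitivity": sens, "specificity": spec,
            "mcc": float(mcc), "f1": f1}


# ---------------------------------------------------------------------------
# selection and cross-validation
# ---------------------------------------------------------------------------

def _cv_score(
    X: np.ndarray, y: np.ndarray, n_folds: int, seed: int
) -> tuple[float, float]:
    """(accuracy, mcc) of the boosted-stump classifier under stratified CV."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    tp = fp = tn = fn = 0
    for train, test in skf.split(X, y):
        mu, sd = _zscore_fit(X[train])
        clf = StumpBoost().fit(_zscore_apply(X[train], mu, sd), y[train])
        pred = clf.predict(_zscore_apply(X[test], mu, sd))
        yt = y[test]
        tp += int(np.sum((pred == 1) & (yt == 1)))
        fp += int(np.sum((pred == 1) & (yt == 0)))
        tn += int(np.sum((pred == 0) & (yt == 0)))
        fn += int(np.sum((pred == 0) & (yt == 1)))
    m = classification_metrics(tp, fp, tn, fn)
    return m["accuracy"], m["mcc"]


def sfs_select(
    table: FeatureTable,
    max_features: int = 20,
    seed: int = 0,
    n_folds: int = 10,
    patience: int | None = None,
    prescreen: int | None = None,
) -> list[str]:
    """Greedy sequential forward selection under the boosted-stump classifier.

    At each step the feature maximizing stratified CV accuracy of the
    current subset is added (ties broken by MCC, then by column order);
    the prefix with the best score is returned.  ``patience`` optionally
    stops growth after that many steps without improvement;
    ``prescreen`` optionally restricts candidates to the top-N features by
    absolute two-sample t statistic (computed on the same data) before the
    wrapper search, for tractability on wide tables.
    """
    if max_features < 1:
        raise ValueError("max_features must be >= 1")
    X, y = table.X, table.y
    n_features = X.shape[1]
    candidates = list(range(n_features))
    if prescreen is not None and prescreen < n_features:
        m1 = X[y == 1].mean(axis=0)
        m0 = X[y == 0].mean(axis=0)
        s = np.sqrt(X[y == 1].var(axis=0, ddof=1) / max((y == 1).sum(), 2)
                    + X[y == 0].var(axis=0, ddof=1) / max((y == 0).sum(), 2))
        tstat = np.abs(m1 - m0) / np.maximum(s, 1e-12)
        top = np.argsort(-tstat, kind="stable")[:prescreen]
        candidates = sorted(top.tolist())

    selected: list[int] = []
    best_prefix: list[int] = []
    best_score = (-np.inf, -np.inf)
    stale = 0
    while len(selected) < min(max_features, len(candidates)):
        step_best = None
        step_score = (-np.inf, -np.inf)
        for j in candidates:
            if j in selected:
                continue
            cols = selected + [j]
            score = _cv_score(X[:, cols], y, n_folds, seed)
            if score > step_score:
                step_score = score
                step_best = j
        if step_best is None:
            break
        selected.append(step_best)
        if step_score > best_score:
            best_score = step_score
            best_prefix = list(selected)
            stale = 0
        else:
            stale += 1
            if patience is not None and stale >= patience:
                break
    return [table.feature_names[j] for j in best_prefix]


@dataclass
class CVResult:
    """Cross-validation outcome: per-fold confusions and aggregate metrics."""

    fold_confusions: list[dict[str, int]]
    metrics_mean: dict[str, float]
    metrics_sd: dict[str, float]
    pooled_metrics: dict[str, float]
    selected_features: list[str]
    n_folds: int
    seed: int
    perm_p: dict[str, float] = field(default_factory=dict)


def cv_evaluate(
    table: FeatureTable,
    features: list[str] | None = None,
    n_folds: int = 10,
    use_smote: bool = True,
    seed: int = 0,
    scale: str = "fold",
    k_neighbors: int = 5,
    nested_sfs: dict | None = None,
) -> CVResult:
    """Stratified k-fold evaluation of the boosted-stump classifier.

    Per fold: z-scoring fit on the training part (``scale='global'``
    replicates fitting on all data), Borderline-SMOTE applied to the
    training part only, 50-round boosted stumps trained, test part
    predicted.  Metrics are reported as mean +/- sd across folds and from
    the pooled confusion counts.  Folds whose test part lacks a class
    contribute NaN to the affected per-fold metric and are dropped from its
    mean with a warning.

    ``nested_sfs`` (a dict of :func:`sfs_select` keyword arguments) enables
    nested selection: the forward search is rerun on the training part of
    every fold, so the test part never influences which features are used.
    It is mutually exclusive with ``features``.
    """
    if nested_sfs is not None and features is not None:
        raise ValueError("nested_sfs and a fixed feature list are mutually exclusive")
    sub = table.subset(features) if features is not None else table
    X, y = sub.X, sub.y
    if scale == "global":
        mu, sd = _zscore_fit(X)
        X = _zscore_apply(X, mu, sd)
    elif scale != "fold":
        raise ValueError("scale must be 'fold' or 'global'")
    n_minority = int(np.bincount(y, minlength=2).min())
    if n_minority < n_folds:
        warnings.warn(
            f"minority class ({n_minority}) smaller than n_folds ({n_folds}); "
            "stratification degrades"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_confusions: list[dict[str, int]] = []
    per_fold = {m: [] for m in METRIC_NAMES}
    for fold_i, (train, test) in enumerate(skf.split(X, y)):
        Xtr, ytr = X[train], y[train]
        Xte = X[test]
        if scale == "fold":
            mu, sd = _zscore_fit(Xtr)
            Xtr, Xte = _zscore_apply(Xtr, mu, sd), _zscore_apply(Xte, mu, sd)
        if nested_sfs is not None:
            inner = FeatureTable(
                [sub.subjects[i] for i in train], sub.feature_names, Xtr, ytr
            )
            chosen = sfs_select(inner, seed=seed, **nested_sfs)
            cols = [sub.feature_names.index(f) for f in chosen]
            Xtr, Xte = Xtr[:, cols], Xte[:, cols]
        if use_smote:
            Xtr, ytr = borderline_smote(Xtr, ytr, k_neighbors=k_neighbors,
                                        seed=seed * 1000 + fold_i)
        clf = StumpBoost().fit(Xtr, ytr)
        pred = clf.predict(Xte)
        yt = y[test]
        conf = {
            "tp": int(np.sum((pred == 1) & (yt == 1))),
            "fp": int(np.sum((pred == 1) & (yt == 0))),
            "tn": int(np.sum((pred == 0) & (yt == 0))),
            "fn": int(np.sum((pred == 0) & (yt == 1))),
        }
        fold_confusions.append(conf)
        m = classification_metrics(**conf)
        for k, v in m.items():
            per_fold[k].append(v)
    metrics_mean, metrics_sd = {}, {}
    for k, vals in per_fold.items():
        arr = np.asarray(vals, dtype=float)
        ok = np.isfinite(arr)
        if not ok.all():
            warnings.warn(f"metric {k} undefined in {int((~ok).sum())} fold(s); "
                          "excluded from the per-fold mean")
        metrics_mean[k] = float(arr[ok].mean()) if ok.any() else float("nan")
        metrics_sd[k] = float(arr[ok].std(ddof=0)) if ok.any() else float("nan")
    totals = {k: sum(c[k] for c in fold_confusions) for k in ("tp", "fp", "tn", "fn")}
    pooled = classification_metrics(**totals)
    return CVResult(
        fold_confusions=fold_confusions,
        metrics_mean=metrics_mean,
        metrics_sd=metrics_sd,
        pooled_metrics=pooled,
        selected_features=list(sub.feature_names),
        n_folds=n_folds,
        seed=seed,
    )


def permutation_pvalue(
    table: FeatureTable,
    features: list[str] | None = None,
    B: int = 5000,
    seed: int = 0,
    n_folds: int = 10,
    use_smote: bool = True,
    scale: str = "fold",
    reselect: bool = False,
    sfs_kwargs: dict | None = None,
) -> dict[str, float]:
    """Label-permutation significance of the cross-validated metrics.

    p = (1 + #{permuted metric >= observed}) / (B + 1) per metric, using
    pooled-confusion metrics.  With ``reselect`` the forward selection is
    rerun inside every permutation replicate (expensive; intended for
    reduced B); otherwise the given feature subset is fixed.
    """
    if B < 1:
        raise ValueError("B must be >= 1")

    def evaluate(t: FeatureTable, s: int) -> dict[str, float]:
        feats = features
        if reselect:
            feats = sfs_select(t, seed=s, n_folds=n_folds, **(sfs_kwargs or {}))
        res = cv_evaluate(t, feats, n_folds=n_folds, use_smote=use_smote,
                          seed=s, scale=scale)
        return res.pooled_metrics

    observed = evaluate(table, seed)
    rng = np.random.default_rng(seed)
    exceed = {k: 0 for k in METRIC_NAMES}
    for b in range(B):
        y_perm = rng.permutation(table.y)
        t_perm = FeatureTable(table.subjects, table.feature_names, table.X, y_perm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            perm = evaluate(t_perm, seed)
        for k in METRIC_NAMES:
            if np.isnan(perm[k]):
                continue
            if perm[k] >= observed[k]:
                exceed[k] += 1
    return {k: (1 + exceed[k]) / (B + 1) for k in METRIC_NAMES}


# ---------------------------------------------------------------------------
# attribution
# ---------------------------------------------------------------------------

@dataclass
class ShapSummary:
    """Per-sample, per-feature Shapley attributions of the classifier margin."""

    values: np.ndarray           # samples x features
    base_value: float
    feature_names: list[str]
    mean_abs: np.ndarray
    top_k: list[str]


def shap_summary(
    model: StumpBoost,
    X: np.ndarray,
    feature_names: list[str],
    background: np.ndarray | None = None,
    k: int = 5,
) -> ShapSummary:
    """Exact Shapley attributions with the additivity (efficiency) property.

    Positive values push the prediction toward the positive (A+) class.
    ``background`` defaults to ``X`` itself.  For every sample,
    base_value + sum(attributions) equals the model margin to machine
    precision (the ensemble is additive over single-feature stumps, so the
    tree-path computation is exact; no sampling is needed).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(feature_names):
        raise ValueError("feature_names length does not match X")
    bg = X if background is None else np.asarray(background, dtype=float)
    phi, base = model.shap_values(X, bg)
    mean_abs = np.abs(phi).mean(axis=0)
    order = np.argsort(-mean_abs, kind="stable")
    top = [feature_names[i] for i in order[:k]]
    return ShapSummary(values=phi, base_value=base, feature_names=list(feature_names),
                       mean_abs=mean_abs, top_k=top)
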