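"""End-to-end orchestration: simulate -> preprocess -> features -> stats -> classify.

A single :class:`PipelineConfig` carries every analysis parameter (band
edges 1-55 Hz, 2-s epochs, 60 retained epochs, five bands, seven
proportional thresholds, 10 CV folds, <= 20 selected features, permutation
replicates) as an explicit default.  Outputs are delimited report tables
(group comparisons, correlations, classification metrics, Shapley ranking)
with rounded presentation values plus full-precision companions, and a run
manifest from which a run reproduces bit-for-bit.
"""

from __future__ import annotations

import json
import logging
import time
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    FeatureTable,
    build_feature_table,
    cv_evaluate,
    permutation_pvalue,
    sfs_select,
    shap_summary,
)
from .boost import StumpBoost
from .connectivity import wpli_matrices
from .core import BAND_NAMES, DEFAULT_BANDS
from .io import metadata_to_frame, read_metadata_table, read_recording, write_cohort
from .network import DEFAULT_THRESHOLDS, network_feature_row, network_feature_vector
from .preprocess import InsufficientEpochsError, preprocess_recording
from .spectral import compute_spectral_features, spectral_feature_row
from .stats import ancova_partial_eta2, partial_correlation_bootstrap
from .synthetic import CohortSpec, child_seed, generate_cohort

log = logging.getLogger("scdeeg")


@dataclass
class PipelineConfig:
    input_dir: str | None = None       # read recordings from here; None -> simulate
    output_dir: str = "scdeeg_output"
    # preprocessing
    filter_lo: float = 1.0
    filter_hi: float = 55.0
    epoch_length: float = 2.0
    amp_thresh_uV: float = 150.0
    n_epochs: int = 60
    preprocess_seed: int = 0
    # features
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    # statistics
    covariate: str = "age"
    n_boot: int = 5000
    # classification
    mode: str = "eeg"
    n_folds: int = 10
    max_features: int = 20
    n_permutations: int = 5000
    use_smote: bool = True
    nested: bool = False
    sfs_prescreen: int | None = 50    # candidate pool for the wrapper search
    sfs_patience: int | None = 3
    classify_seed: int = 0
    global_scaling: bool = False       # z-score on all data before CV (leaky; for comparability with studies that scale first)
    # simulation
    simulate: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.thresholds = tuple(cfg.thresholds)
        return cfg


def simulate_cohort(config: PipelineConfig):
    kwargs = dict(config.simulate)
    kwargs.setdefault("seed", config.seed)
    spec = CohortSpec(**kwargs)
    return generate_cohort(spec), spec


def extract_features(
    cohort,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, list[str]]:
    """Preprocess every subject and compute spectral + network feature frames.

    Returns (spectral, network, meta, failed_subjects); subjects that fail
    epoch selection are dropped with a log entry.
    """
    spectral_rows, network_rows, metas, failed = {}, {}, [], []
    for i, (rec, meta) in enumerate(cohort):
        try:
            es = preprocess_recording(
                rec,
                lo=config.filter_lo,
                hi=config.filter_hi,
                epoch_length=config.epoch_length,
                amp_thresh_uV=config.amp_thresh_uV,
                n_select=config.n_epochs,
                seed=child_seed(config.preprocess_seed, i),
            )
        except InsufficientEpochsError as exc:
            log.warning("skipping subject: %s", exc)
            failed.append(meta.subject_id)
            continue
        spectral_rows[meta.subject_id] = spectral_feature_row(
            compute_spectral_features(es)
        )
        row: dict[str, float] = {}
        for band, cm in wpli_matrices(es).items():
            row.update(network_feature_row(
                network_feature_vector(cm, config.thresholds)
            ))
        network_rows[meta.subject_id] = row
        metas.append(meta)
    for group in ("A_plus", "A_minus"):
        n = sum(1 for m in metas if m.group == group)
        if n < 4:
            raise RuntimeError(f"fewer than 4 usable subjects in group {group}")
    spectral = pd.DataFrame.from_dict(spectral_rows, orient="index")
    network = pd.DataFrame.from_dict(network_rows, orient="index")
    meta_df = metadata_to_frame(metas).set_index("subject_id")
    return spectral, network, meta_df, failed


def group_comparison_report(
    spectral: pd.DataFrame, network: pd.DataFrame, meta: pd.DataFrame,
    covariate: str = "age",
) -> pd.DataFrame:
    """ANCOVA (covariate-adjusted) contrast of every EEG feature between groups."""
    eeg = spectral.join(network).loc[meta.index]
    is_pos = (meta["group"] == "A_plus").to_numpy()
    cov = meta[covariate].to_numpy(dtype=float)
    rows = []
    for col in eeg.columns:
        y = eeg[col].to_numpy(dtype=float)
        try:
            res = ancova_partial_eta2(y, is_pos.astype(int), cov)
        except ValueError:
            continue
        rows.append({
            "feature": col,
            "mean_pos": float(y[is_pos].mean()),
            "sd_pos": float(y[is_pos].std(ddof=1)),
            "mean_neg": float(y[~is_pos].mean()),
            "sd_neg": float(y[~is_pos].std(ddof=1)),
            "F": res.statistic,
            "partial_eta2": res.effect_size,
            "p": res.p_value,
        })
    return pd.DataFrame(rows)


def correlation_report(
    spectral: pd.DataFrame, meta: pd.DataFrame,
    covariate: str = "age", n_boot: int = 5000, seed: int = 0,
) -> pd.DataFrame:
    """Age-adjusted partial correlations: global band power vs cognitive scores."""
    score_cols = [c for c in meta.columns
                  if c not in ("group", "age", "sex", "education_years", "apoe4")
                  and pd.api.types.is_numeric_dtype(meta[c])]
    cov = meta[covariate].to_numpy(dtype=float)
    rows = []
    for bi, band in enumerate(BAND_NAMES):
        x = spectral.loc[meta.index, f"{band}_power_Global"].to_numpy(dtype=float)
        for si, score in enumerate(score_cols):
            y = meta[score].to_numpy(dtype=float)
            res = partial_correlation_bootstrap(
                x, y, cov, n_boot=n_boot, seed=child_seed(seed, bi, si)
            )
            rows.append({
                "eeg_feature": f"{band}_power_Global", "score": score,
                "r": res.r, "p": res.p_value,
                "ci_lo": res.ci95[0], "ci_hi": res.ci95[1], "n": res.n,
            })
    return pd.DataFrame(rows)


def classification_report(
    spectral: pd.DataFrame, network: pd.DataFrame, meta: pd.DataFrame,
    config: PipelineConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run EEG-mode and demographic-mode classification; return metrics + SHAP tables."""
    scale = "global" if config.global_scaling else "fold"
    rows = []
    shap_table = pd.DataFrame()
    for mode in ("eeg", "demographic"):
        table = build_feature_table(spectral, network, meta, mode=mode)
        selected = sfs_select(
            table,
            max_features=config.max_features,
            seed=config.classify_seed,
            n_folds=config.n_folds,
            patience=config.sfs_patience,
            prescreen=config.sfs_prescreen,
        )
        res = cv_evaluate(
            table, selected, n_folds=config.n_folds,
            use_smote=config.use_smote, seed=config.classify_seed, scale=scale,
        )
        perm = permutation_pvalue(
            table, selected, B=config.n_permutations, seed=config.classify_seed,
            n_folds=config.n_folds, use_smote=config.use_smote, scale=scale,
            reselect=config.nested,
        )
        row = {"case": mode, "n_selected": len(selected)}
        for m in ("accuracy", "sensitivity", "specificity", "mcc", "f1"):
            row[m] = res.metrics_mean[m]
            row[f"{m}_sd"] = res.metrics_sd[m]
            row[f"{m}_perm_p"] = perm[m]
        rows.append(row)
        if mode == "eeg":
            sub = table.subset(selected)
            mu, sd = sub.X.mean(axis=0), np.maximum(sub.X.std(axis=0), 1e-12)
            Z = (sub.X - mu) / sd
            model = StumpBoost().fit(Z, sub.y)
            summ = shap_summary(model, Z, selected)
            shap_table = pd.DataFrame({
                "feature": summ.feature_names,
                "mean_abs_shap": summ.mean_abs,
            }).sort_values("mean_abs_shap", ascending=False, ignore_index=True)
    return pd.DataFrame(rows), shap_table


def write_report_tables(results: dict[str, pd.DataFrame], out_dir: str | Path) -> list[Path]:
    """Write each result table twice: rounded presentation TSV + full precision.

    Rounding (3 decimals) is applied only at the presentation layer; the
    ``*_full.tsv`` companion keeps full float precision.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for name, df in results.items():
        pres = out_dir / f"{name}.tsv"
        full = out_dir / f"{name}_full.tsv"
        df.round(3).to_csv(pres, sep="\t", index=False)
        df.to_csv(full, sep="\t", index=False, float_format="%.17g")
        written += [pres, full]
    return written


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns the results bundle (also written to disk)."""
    t0 = time.time()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.input_dir is None:
        log.info("simulating synthetic cohort")
        cohort, spec = simulate_cohort(config)
    else:
        in_dir = Path(config.input_dir)
        meta_df = read_metadata_table(in_dir / "metadata.tsv")
        from .synthetic import SubjectMeta

        cohort = []
        for _, r in meta_df.iterrows():
            rec_path = next(in_dir.glob(f"{r['subject_id']}.*"))
            rec = read_recording(rec_path)
            score_cols = [c for c in meta_df.columns if c not in
                          ("subject_id", "group", "age", "sex", "education_years", "apoe4")]
            cohort.append((rec, SubjectMeta(
                subject_id=str(r["subject_id"]), group=str(r["group"]),
                age=float(r["age"]), sex=str(r.get("sex", "female")),
                education=float(r.get("education_years", 0.0)),
                apoe4=bool(r.get("apoe4", False)),
                cognitive_scores={c: float(r[c]) for c in score_cols},
            )))
        spec = None

    spectral, network, meta, failed = extract_features(cohort, config)
    log.info("features extracted for %d subjects (%d failed)", len(meta), len(failed))

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        comparisons = group_comparison_report(spectral, network, meta, config.covariate)
        correlations = correlation_report(
            spectral, meta, config.covariate, config.n_boot, config.seed
        )
        metrics, shap_rank = classification_report(spectral, network, meta, config)

    results = {
        "spectral_features": spectral.reset_index(names="subject_id"),
        "network_features": network.reset_index(names="subject_id"),
        "group_comparisons": comparisons,
        "correlations": correlations,
        "classification_metrics": metrics,
        "shap_ranking": shap_rank,
    }
    write_report_tables(results, out_dir)
    manifest = {
        "package_version": __version__,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "failed_subjects": failed,
        "n_subjects": len(meta),
        "elapsed_s": round(time.time() - t0, 2),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    log.info("pipeline finished in %.1f s", manifest["elapsed_s"])
    results["manifest"] = manifest
    return results
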