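"""End-to-end orchestration: data -> segments -> features -> reports.

``run_pipeline`` reproduces the whole study design on a directory of
recordings (WFDB or fixture dialect) or on simulated data: pre-processing
and exclusion accounting, the per-segment feature table, a univariate
report (AUC, Youden cutoff and confusion metrics per feature), a
model-comparison report over univariate/multivariate logistic regressions,
and a bootstrap comparison of the strongest models.  Everything is
deterministic given the configured seeds and a manifest records the
configuration hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classification import apply_cutoff, confusion_metrics, roc_auc, youden_cutoff
from .errors import AfhrvError
from .io import (FEATURE_TABLE_COLUMNS, read_beat_annotations,
                 write_feature_table)
from .models import (DEFAULT_FEATURE_SETS, SplitSpec, bootstrap_metrics,
                     compare_models, fit_logistic, split_train_test)
from .prrx import prrx_ms, prrx_rel
from .runs import rr_entropies
from .segmentation import Segment, preprocess_record

log = logging.getLogger(__name__)

#: models singled out for bootstrap comparison: best single, pair, triple
BOOTSTRAP_MODEL_SETS = [["pRR3.25"], ["pRR3.25", "pRR30"], ["pRR30", "pRR3.25", "H"]]


@dataclass
class RunConfig:
    mode: str = "simulate"  # simulate | fixture_dir | wfdb_dir
    input_dir: str | None = None
    out_dir: str = "afhrv_run"
    window_s: float = 60.0
    rr_min_ms: float = 240.0
    rr_max_ms: float = 3000.0
    excluded_max_ms: float = 1800.0
    retained_min_ms: float = 58_000.0
    prr_abs_ms: float = 30.0
    prr_rel_pct: float = 3.25
    split_ratio: float = 2.0 / 3.0
    split_mode: str = "by_record"
    bootstrap_b: int = 1000
    seed: int = 0
    n_sr: int = 100
    n_af: int = 100
    artifact_rate: float = 0.0
    feature_sets: list[list[str]] = field(default_factory=lambda: [list(s) for s in DEFAULT_FEATURE_SETS])

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def extract_features(segments: list[Segment], prr_abs_ms: float = 30.0,
                     prr_rel_pct: float = 3.25) -> pd.DataFrame:
    """Per-segment feature rows (valid intervals only, concatenated in order)."""
    rows = []
    for seg in segments:
        rr = seg.valid_durations
        if rr.size < 2:
            continue
        ent = rr_entropies(rr)
        rows.append({
            "record_id": seg.record_id,
            "window_index": seg.window_index,
            "class_label": seg.class_label,
            "pRR30": prrx_ms(rr, prr_abs_ms).percentage,
            "pRR3.25": prrx_rel(rr, prr_rel_pct).percentage,
            "H": ent.H, "HAR": ent.HAR, "HDR": ent.HDR, "HNR": ent.HNR,
            "mean_rr": float(rr.mean()),
            "n_intervals": int(rr.size),
        })
    return pd.DataFrame(rows, columns=FEATURE_TABLE_COLUMNS)


def univariate_report(train: pd.DataFrame, test: pd.DataFrame,
                      features: list[str]) -> pd.DataFrame:
    """Per-feature AUC + Youden cutoff on the training set, confusion metrics
    on the test set at that cutoff (the single-parameter report)."""
    rows = []
    for feat in features:
        labels_tr = train["class_label"].to_numpy()
        cut = youden_cutoff(train[feat].to_numpy(), labels_tr)
        auc = roc_auc(train[feat].to_numpy(), labels_tr).auc
        pred = apply_cutoff(test[feat].to_numpy(), cut)
        cm = confusion_metrics(pred, test["class_label"].to_numpy())
        rows.append({
            "feature": feat, "auc": auc, "cutoff": cut.cutoff,
            "direction": cut.direction,
            "accuracy": cm.accuracy, "sensitivity": cm.sensitivity,
            "specificity": cm.specificity, "ppv": cm.ppv, "npv": cm.npv,
            "dor": cm.dor,
        })
    return pd.DataFrame(rows)


def _collect_segments(config: RunConfig) -> tuple[pd.DataFrame, dict]:
    if config.mode == "simulate":
        from .synthetic import DatasetSpec, gen_labelled_dataset
        spec = DatasetSpec(n_sr=config.n_sr, n_af=config.n_af, seed=config.seed,
                           artifact_rate=config.artifact_rate)
        segments, table = gen_labelled_dataset(spec)
        accounting = {"retained": sum(s.retained for s in segments),
                      "total_windows": len(segments)}
        for s in segments:
            if not s.retained:
                accounting[s.exclusion_reason] = accounting.get(s.exclusion_reason, 0) + 1
        return table, accounting
    if config.mode not in ("fixture_dir", "wfdb_dir"):
        raise AfhrvError(f"unknown input mode {config.mode!r}")
    if not config.input_dir:
        raise AfhrvError(f"mode {config.mode} requires input_dir")
    dialect = "fixture" if config.mode == "fixture_dir" else "wfdb"
    pattern = "*.csv" if dialect == "fixture" else "*.atr"
    paths = sorted(Path(config.input_dir).glob(pattern))
    if not paths:
        raise AfhrvError(f"no {pattern} recordings under {config.input_dir}")
    tables, accounting = [], {}
    for p in paths:
        stream = read_beat_annotations(p, dialect=dialect)
        retained, acc = preprocess_record(
            stream, window_s=config.window_s, lo_ms=config.rr_min_ms,
            hi_ms=config.rr_max_ms, excluded_max_ms=config.excluded_max_ms,
            retained_min_ms=config.retained_min_ms)
        log.info("record %s: %s", stream.record_id, acc)
        tables.append(extract_features(retained, config.prr_abs_ms, config.prr_rel_pct))
        for k, v in acc.items():
            accounting[k] = accounting.get(k, 0) + v
    table = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=FEATURE_TABLE_COLUMNS)
    return table, accounting


def run_pipeline(config: RunConfig) -> Path:
    """Run the full study; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=logging.INFO,
                        filename=out / "run.log", filemode="w", force=True)
    table, accounting = _collect_segments(config)

    if table.empty:
        reasons = {k: v for k, v in accounting.items()
                   if k not in ("retained", "total_windows")}
        dominant = max(reasons, key=reasons.get) if reasons else "no windows"
        raise AfhrvError(f"no retained segments (dominant exclusion: {dominant})")

    write_feature_table(table, out / "feature_table.csv")
    (out / "accounting.json").write_text(json.dumps(accounting, indent=2, sort_keys=True))

    features = ["pRR30", "pRR3.25", "H", "HAR", "HDR", "HNR"]
    classes = set(table["class_label"])
    if classes == {"AF", "SR"}:
        split = SplitSpec(ratio=config.split_ratio, mode=config.split_mode,
                          seed=config.seed)
        train, test = split_train_test(table, split)
        univariate_report(train, test, features).to_csv(
            out / "table1_univariate.csv", index=False, float_format="%.6g")
        compare_models(config.feature_sets, train, test).to_csv(
            out / "table2_models.csv", index=False, float_format="%.6g")
        models = {" & ".join(fs): fit_logistic(train, fs) for fs in BOOTSTRAP_MODEL_SETS}
        comparisons, pvals = bootstrap_metrics(models, test, b=config.bootstrap_b,
                                               seed=config.seed)
        pd.DataFrame([{
            "model": c.model_name, "metric": c.metric_name, "point": c.point,
            "ci_low": c.ci_low, "ci_high": c.ci_high,
        } for c in comparisons]).to_csv(out / "bootstrap.csv", index=False,
                                        float_format="%.6g")
        pvals.to_csv(out / "bootstrap_pvalues.csv", index=False, float_format="%.6g")
    else:
        msg = f"only one class present ({classes}); ROC/model reports skipped"
        log.warning(msg)
        (out / "SKIPPED_REPORTS.txt").write_text(msg + "\n")

    cfg = config.to_dict()
    manifest = {
        "package_version": __version__,
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "seed": config.seed,
        "n_segments": int(len(table)),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out
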