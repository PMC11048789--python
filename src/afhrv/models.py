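"""Train/test splitting, logistic models and bootstrap model comparison.

The split is 2:1 by default and grouped by recording (``by_record``), so no
recording contributes segments to both sides; a plain ``by_segment`` split
is available for comparison.  Logistic regressions are unpenalized maximum
likelihood on features standardized by the training mean and SD (AF coded
1); a coefficient cap guards against complete separation.  Model comparison
uses a non-parametric bootstrap of the test set (B = 1000): the same
resample indices are applied to every model so that per-resample metric
differences are paired.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression

from .classification import ConfusionMetrics, confusion_metrics, roc_auc, youden_cutoff, apply_cutoff
from .errors import ValidationError

log = logging.getLogger(__name__)

FEATURES = ["pRR30", "pRR3.25", "H", "HAR", "HDR", "HNR"]

#: the univariate and multivariate feature sets of the model-comparison table
DEFAULT_FEATURE_SETS: list[list[str]] = (
    [[f] for f in FEATURES]
    + [["pRR3.25", "pRR30"]]
    + [["pRR3.25", e] for e in ["H", "HAR", "HDR", "HNR"]]
    + [["pRR30", e] for e in ["H", "HAR", "HDR", "HNR"]]
    + [["pRR30", "pRR3.25", e] for e in ["H", "HAR", "HDR", "HNR"]]
    + [["HNR", "HAR", "HDR"]]
)

_COEF_CAP = 30.0  # on standardized features; hit only under (near-)separation


@dataclass(frozen=True)
class SplitSpec:
    ratio: float = 2.0 / 3.0  # train fraction
    mode: str = "by_record"  # or "by_segment"
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.ratio < 1.0:
            raise ValidationError("split ratio must be in (0, 1)")
        if self.mode not in ("by_record", "by_segment"):
            raise ValidationError(f"unknown split mode {self.mode!r}")


@dataclass
class FittedLogistic:
    feature_names: list[str]
    coefficients: np.ndarray  # per feature, on standardized scale
    intercept: float
    means: np.ndarray
    sds: np.ndarray

    def predict_proba(self, rows: pd.DataFrame) -> np.ndarray:
        missing = [f for f in self.feature_names if f not in rows.columns]
        if missing:
            raise ValidationError(f"missing feature columns {missing}")
        x = (rows[self.feature_names].to_numpy(dtype=float) - self.means) / self.sds
        z = x @ self.coefficients + self.intercept
        return 1.0 / (1.0 + np.exp(-z))


@dataclass(frozen=True)
class BootstrapComparison:
    metric_name: str
    model_name: str
    values: np.ndarray  # per-resample, length B
    point: float
    ci_low: float  # 2.5th percentile
    ci_high: float  # 97.5th percentile


@dataclass(frozen=True)
class EvalResult:
    auc: float
    confusion: ConfusionMetrics
    fp_pct: float  # FP as % of the test set
    fn_pct: float


def split_train_test(rows: pd.DataFrame, spec: SplitSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deterministic train/test split; ``by_record`` keeps recordings intact."""
    rng = np.random.default_rng(spec.seed)
    n = len(rows)
    if spec.mode == "by_segment":
        perm = rng.permutation(n)
        n_train = int(round(spec.ratio * n))
        train = rows.iloc[np.sort(perm[:n_train])]
        test = rows.iloc[np.sort(perm[n_train:])]
    else:
        # stratify by each record's majority class so both sides see both
        # classes whenever at least two records per class exist
        sizes = rows["record_id"].value_counts()
        majority = rows.groupby("record_id")["class_label"].agg(
            lambda s: s.value_counts().idxmax())
        train_records: list = []
        for cls in sorted(majority.unique()):
            records = np.sort(majority.index[majority == cls].to_numpy())
            rng.shuffle(records)
            target = spec.ratio * sizes[records].sum()
            acc = 0
            for i, rec in enumerate(records):
                if acc >= target or i == len(records) - 1:
                    break  # leave at least one record per class for the test side
                train_records.append(rec)
                acc += sizes[rec]
        in_train = rows["record_id"].isin(train_records)
        train, test = rows[in_train], rows[~in_train]
    for name, part in (("train", train), ("test", test)):
        classes = set(part["class_label"])
        if classes != {"AF", "SR"}:
            raise ValidationError(
                f"{name} side lacks a class ({classes}); reseed the split")
    return train, test


def fit_logistic(train: pd.DataFrame, features: list[str],
                 label_col: str = "class_label") -> FittedLogistic:
    """Unpenalized logistic regression on standardized features, AF coded 1."""
    if not features:
        raise ValidationError("empty feature set")
    missing = [f for f in features if f not in train.columns]
    if missing:
        raise ValidationError(f"missing feature columns {missing}")
    x = train[features].to_numpy(dtype=float)
    y = (train[label_col].to_numpy() == "AF").astype(int)
    if y.min() == y.max():
        raise ValidationError("training data must contain both classes")
    means = x.mean(axis=0)
    sds = x.std(axis=0, ddof=0)
    if (sds == 0).any():
        bad = [f for f, s in zip(features, sds) if s == 0]
        raise ValidationError(f"constant feature(s) {bad} cannot be standardized")
    xs = (x - means) / sds
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        # C=inf -> unpenalized maximum likelihood
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=2000)
        clf.fit(xs, y)
    coef = clf.coef_[0].copy()
    intercept = float(clf.intercept_[0])
    z = xs @ coef + intercept
    separated = z[y == 1].min() > z[y == 0].max() or z[y == 1].max() < z[y == 0].min()
    if separated or np.abs(coef).max() > _COEF_CAP or abs(intercept) > _COEF_CAP:
        warnings.warn("(quasi-)separation detected: capping logistic coefficients",
                      stacklevel=2)
        coef = np.clip(coef, -_COEF_CAP, _COEF_CAP)
        intercept = float(np.clip(intercept, -_COEF_CAP, _COEF_CAP))
    return FittedLogistic(feature_names=list(features), coefficients=coef,
                          intercept=intercept, means=means, sds=sds)


def evaluate_model(model: FittedLogistic, test: pd.DataFrame,
                   threshold: float | str = 0.5,
                   train: pd.DataFrame | None = None) -> EvalResult:
    """Test-set AUC and confusion metrics for a fitted model.

    ``threshold`` is a probability (default 0.5) or ``"youden"`` to take the
    Youden-optimal cutoff of the training probabilities (requires ``train``).
    """
    proba = model.predict_proba(test)
    labels = test["class_label"].to_numpy()
    auc = roc_auc(proba, labels).auc
    if threshold == "youden":
        if train is None:
            raise ValidationError("threshold='youden' requires the training rows")
        cut = youden_cutoff(model.predict_proba(train), train["class_label"].to_numpy())
        pred = apply_cutoff(proba, cut)
    else:
        pred = np.where(proba >= float(threshold), "AF", "SR")
    cm = confusion_metrics(pred, labels)
    n = len(test)
    return EvalResult(auc=auc, confusion=cm,
                      fp_pct=100.0 * cm.fp / n, fn_pct=100.0 * cm.fn / n)


def _resample_metrics(proba: np.ndarray, labels: np.ndarray,
                      threshold: float = 0.5) -> dict[str, float]:
    cm = confusion_metrics(np.where(proba >= threshold, "AF", "SR"), labels)
    return {
        "auc": roc_auc(proba, labels).auc,
        "accuracy": cm.accuracy,
        "sensitivity": cm.sensitivity,
        "specificity": cm.specificity,
        "dor": cm.dor,
        "fn": float(cm.fn),
        "fp": float(cm.fp),
    }


BOOTSTRAP_METRICS = ("auc", "accuracy", "sensitivity", "specificity", "dor", "fn", "fp")


def bootstrap_metrics(
    models: dict[str, FittedLogistic],
    test: pd.DataFrame,
    b: int = 1000,
    seed: int = 0,
    threshold: float = 0.5,
) -> tuple[list[BootstrapComparison], pd.DataFrame]:
    """Bootstrap the test set B times (same indices for every model).

    Returns per-model percentile CIs and a paired-comparison table with
    two-sided p-values, ``p = 2 * min(frac(diff <= 0), frac(diff >= 0))``
    floored at 1/B and capped at 1.
    """
    if not models:
        raise ValidationError("need at least one model")
    if len(test) == 0:
        raise ValidationError("empty test set")
    rng = np.random.default_rng(seed)
    labels = test["class_label"].to_numpy()
    n = len(test)
    probas = {name: m.predict_proba(test) for name, m in models.items()}
    values = {name: {m: np.empty(b) for m in BOOTSTRAP_METRICS} for name in models}
    for rep in range(b):
        for _attempt in range(1000):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if (lab == "AF").any() and (lab == "SR").any():
                break
            log.warning("bootstrap resample %d missing a class; redrawn", rep)
        else:
            raise ValidationError("could not draw a two-class bootstrap resample")
        for name in models:
            got = _resample_metrics(probas[name][idx], lab, threshold)
            for m in BOOTSTRAP_METRICS:
                values[name][m][rep] = got[m]

    comparisons = []
    for name, m in models.items():
        point = _resample_metrics(probas[name], labels, threshold)
        for metric in BOOTSTRAP_METRICS:
            v = values[name][metric]
            comparisons.append(BootstrapComparison(
                metric_name=metric, model_name=name, values=v,
                point=point[metric],
                ci_low=float(np.percentile(v, 2.5)),
                ci_high=float(np.percentile(v, 97.5))))

    rows = []
    names = list(models)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            for metric in BOOTSTRAP_METRICS:
                diff = values[names[i]][metric] - values[names[j]][metric]
                p = 2.0 * min((diff <= 0).mean(), (diff >= 0).mean())
                p = min(1.0, max(p, 1.0 / b))
                rows.append({"model_a": names[i], "model_b": names[j],
                             "metric": metric, "mean_diff": float(diff.mean()),
                             "p_value": p})
    return comparisons, pd.DataFrame(rows)


def compare_models(
    feature_sets: list[list[str]],
    train: pd.DataFrame,
    test: pd.DataFrame,
    threshold: float | str = 0.5,
) -> pd.DataFrame:
    """One evaluation row per feature set (AUC, accuracy, DOR, FP/FN rates)."""
    rows = []
    for features in feature_sets:
        if not features:
            raise ValidationError("empty feature set")
        deduped = list(dict.fromkeys(features))
        if len(deduped) < len(features):
            warnings.warn(f"duplicate features in {features}; deduplicated",
                          stacklevel=2)
        model = fit_logistic(train, deduped)
        res = evaluate_model(model, test, threshold=threshold, train=train)
        rows.append({
            "features": " & ".join(deduped),
            "auc": res.auc,
            "accuracy": res.confusion.accuracy / 100.0,
            "dor": res.confusion.dor,
            "fp_plus_fn_pct": res.fp_pct + res.fn_pct,
            "fp_pct": res.fp_pct,
            "fn_pct": res.fn_pct,
        })
    return pd.DataFrame(rows)
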