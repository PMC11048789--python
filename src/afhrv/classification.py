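"""ROC/AUC analysis, Youden optimal cutoff, confusion metrics and feature correlations.

AF is always the positive class.  Each score's orientation is chosen
automatically so that AUC >= 0.5 and recorded as a direction (``af_if_ge``
when high scores indicate AF, ``af_if_le`` otherwise); the threshold grid
for the Youden scan is the set of midpoints between adjacent distinct
observed values plus +/-infinity, which makes the chosen cutoff independent
of which side of a gap an observed value sits on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn import metrics as skm

from .errors import ValidationError


@dataclass(frozen=True)
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    direction: str  # "af_if_ge" | "af_if_le"


@dataclass(frozen=True)
class CutoffResult:
    cutoff: float
    direction: str
    youden_j: float
    sensitivity: float  # fraction, at the cutoff (training data)
    specificity: float


@dataclass(frozen=True)
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float  # all percentages in [0, 100]
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    dor: float


def _check_classes(labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels)
    is_af = y == "AF" if y.dtype.kind in ("U", "S", "O") else y.astype(bool)
    if is_af.all() or (~is_af).all():
        raise ValidationError("both classes (AF and SR) must be present")
    return is_af


def roc_auc(scores, labels) -> RocResult:
    """ROC curve over all distinct thresholds and trapezoid AUC.

    The AUC equals the pairwise probability P(score_AF > score_SR) + 0.5
    P(tie) in the AF-high orientation; the reported orientation is flipped
    when that probability is below 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    if not np.isfinite(scores).all():
        raise ValidationError("scores must be finite")
    is_af = _check_classes(labels)
    fpr, tpr, _ = skm.roc_curve(is_af, scores)
    auc = float(skm.auc(fpr, tpr))
    if auc >= 0.5:
        return RocResult(fpr=fpr, tpr=tpr, auc=auc, direction="af_if_ge")
    fpr, tpr, _ = skm.roc_curve(is_af, -scores)
    return RocResult(fpr=fpr, tpr=tpr, auc=float(skm.auc(fpr, tpr)),
                     direction="af_if_le")


def _midpoint_thresholds(values: np.ndarray) -> np.ndarray:
    v = np.unique(values)
    mids = (v[:-1] + v[1:]) / 2.0
    return np.concatenate(([-np.inf], mids, [np.inf]))


def youden_cutoff(scores, labels) -> CutoffResult:
    """Cutoff maximizing J = sensitivity + specificity - 1.

    Ties are broken by higher sensitivity, then by the smaller cutoff value.
    """
    scores = np.asarray(scores, dtype=float)
    is_af = _check_classes(labels)
    direction = roc_auc(scores, labels).direction
    s = scores if direction == "af_if_ge" else -scores
    thresholds = _midpoint_thresholds(s)
    pred = s[None, :] >= thresholds[:, None]  # (T, N) predicted AF
    n_af, n_sr = int(is_af.sum()), int((~is_af).sum())
    sens = (pred & is_af[None, :]).sum(axis=1) / n_af
    spec = (~pred & ~is_af[None, :]).sum(axis=1) / n_sr
    j = sens + spec - 1.0
    # lexicographic argmax: J, then sensitivity, then smaller |cutoff| order
    order = np.lexsort((np.arange(len(thresholds))[::-1], sens, j))
    best = order[-1]
    cutoff = thresholds[best] if direction == "af_if_ge" else -thresholds[best]
    return CutoffResult(cutoff=float(cutoff), direction=direction,
                        youden_j=float(j[best]), sensitivity=float(sens[best]),
                        specificity=float(spec[best]))


def apply_cutoff(scores, cut: CutoffResult) -> np.ndarray:
    """Predicted labels ('AF'/'SR') for scores under a fitted cutoff."""
    scores = np.asarray(scores, dtype=float)
    if cut.direction == "af_if_ge":
        pred_af = scores >= cut.cutoff
    else:
        pred_af = scores <= cut.cutoff
    return np.where(pred_af, "AF", "SR")


def confusion_metrics(predictions, labels) -> ConfusionMetrics:
    """Confusion-matrix metrics with AF positive; DOR uses the Haldane–Anscombe
    0.5 correction on every cell when any cell is zero (keeps DOR finite)."""
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    if predictions.shape != labels.shape:
        raise ValidationError("predictions and labels must have equal length")
    pred_af = predictions == "AF"
    true_af = labels == "AF"
    tp = int((pred_af & true_af).sum())
    fp = int((pred_af & ~true_af).sum())
    tn = int((~pred_af & ~true_af).sum())
    fn = int((~pred_af & true_af).sum())
    total = tp + fp + tn + fn

    def pct(num, den):
        return 100.0 * num / den if den else float("nan")

    cells = np.array([tp, fp, tn, fn], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    ctp, cfp, ctn, cfn = cells
    return ConfusionMetrics(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=pct(tp + tn, total),
        sensitivity=pct(tp, tp + fn),
        specificity=pct(tn, tn + fp),
        ppv=pct(tp, tp + fp),
        npv=pct(tn, tn + fn),
        dor=float(ctp * ctn / (cfp * cfn)),
    )


def spearman_matrix(features: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Spearman rho and two-sided p-value matrices over feature columns.

    Average ranks for ties; a constant column yields NaN for its pairs.
    Computed per rhythm class by the caller (the SR and AF matrices differ).
    """
    if len(features) < 3:
        raise ValidationError("need at least 3 segments for correlations")
    cols = list(features.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    with np.errstate(invalid="ignore"):
        for i in range(k):
            for j in range(i + 1, k):
                r, p = stats.spearmanr(features[cols[i]], features[cols[j]])
                rho[i, j] = rho[j, i] = r
                pval[i, j] = pval[j, i] = p
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))
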