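"""Performance and agreement statistics.

AUC (Mann-Whitney with tie credit), threshold metrics with percentile
confidence intervals over cross-validation replicates or bootstrap
resamples, the paired DeLong test via the placement-value covariance
estimator, Dice/Jaccard segmentation overlap, and Pearson feature-label
correlation maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)


@dataclass
class RocResult:
    auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    threshold: float

    def as_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "threshold": self.threshold,
        }


@dataclass
class DelongResult:
    auc_a: float
    auc_b: float
    var_diff: float
    z: float
    p_value: float

    def as_dict(self) -> dict:
        return {
            "auc_a": self.auc_a,
            "auc_b": self.auc_b,
            "var_diff": self.var_diff,
            "z": self.z,
            "p_value": self.p_value,
        }


@dataclass
class OverlapResult:
    dice: float
    jaccard: float


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC with 0.5 credit for ties."""
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def _threshold_metrics(scores, labels, threshold) -> tuple[float, float, float]:
    pred = np.asarray(scores) >= threshold
    labels = np.asarray(labels, dtype=bool)
    tp = np.sum(pred & labels)
    tn = np.sum(~pred & ~labels)
    acc = (tp + tn) / len(labels)
    sens = tp / max(labels.sum(), 1)
    spec = tn / max((~labels).sum(), 1)
    return float(acc), float(sens), float(spec)


def performance_summary(
    scores: np.ndarray,
    labels: np.ndarray,
    threshold: float = 0.5,
    replicate_scores: np.ndarray | None = None,
    n_boot: int = 200,
    seed: int = 0,
) -> RocResult:
    """Median and 95% percentile CI of AUC/accuracy/sensitivity/specificity.

    Replicates come either from repeated-CV score matrices
    (``replicate_scores``, shape (R, n)) evaluated against the fixed
    labels, or from bootstrap resampling of (scores, labels).  Degenerate
    replicates with one class are skipped (logged).
    """
    labels = np.asarray(labels, dtype=int)
    if replicate_scores is not None:
        reps = [(np.asarray(s, dtype=float), labels) for s in replicate_scores]
    else:
        rng = np.random.default_rng(seed)
        scores = np.asarray(scores, dtype=float)
        n = len(labels)
        reps = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            reps.append((scores[idx], labels[idx]))
    rows = []
    skipped = 0
    for s, lab in reps:
        if lab.min() == lab.max():
            skipped += 1
            continue
        acc, sens, spec = _threshold_metrics(s, lab, threshold)
        rows.append((roc_auc(s, lab), acc, sens, spec))
    if skipped:
        logger.info("skipped %d one-class replicates", skipped)
    arr = np.asarray(rows)

    def med_ci(col: np.ndarray) -> tuple[float, tuple[float, float]]:
        return float(np.median(col)), (
            float(np.percentile(col, 2.5)),
            float(np.percentile(col, 97.5)),
        )

    auc_m, auc_ci = med_ci(arr[:, 0])
    acc_m, acc_ci = med_ci(arr[:, 1])
    sens_m, sens_ci = med_ci(arr[:, 2])
    spec_m, spec_ci = med_ci(arr[:, 3])
    return RocResult(
        auc_m, auc_ci, acc_m, acc_ci, sens_m, sens_ci, spec_m, spec_ci, threshold
    )


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _placements(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (positives) and V01 (negatives)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    pos_r = _midrank(pos)
    neg_r = _midrank(neg)
    auc = (all_r[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v10 = (all_r[:m] - pos_r) / n
    v01 = 1.0 - (all_r[m:] - neg_r) / m
    return auc, v10, v01


def delong_test(
    scores_a: np.ndarray, scores_b: np.ndarray, labels: np.ndarray
) -> DelongResult:
    """Paired DeLong comparison of two correlated AUCs.

    Uses the placement-value covariance estimator; two-sided normal
    p-value.  Zero variance with equal AUCs (e.g. identical score vectors)
    yields p = 1.
    """
    labels = np.asarray(labels, dtype=int)
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape or scores_a.shape != labels.shape:
        raise ValueError("paired scores and labels must have equal length")
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    auc_a, v10_a, v01_a = _placements(scores_a, labels)
    auc_b, v10_b, v01_b = _placements(scores_b, labels)
    m, n = len(v10_a), len(v01_a)
    s10 = np.cov(np.stack([v10_a, v10_b]), ddof=1)
    s01 = np.cov(np.stack([v01_a, v01_b]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
        p = 1.0 if diff == 0 else 0.0
    else:
        z = diff / np.sqrt(var_diff)
        p = float(2.0 * stats.norm.sf(abs(z)))
    return DelongResult(float(auc_a), float(auc_b), var_diff, float(z), p)


def dice_jaccard(mask_a: np.ndarray, mask_b: np.ndarray) -> OverlapResult:
    """Dice = 2|A∩B| / (|A|+|B|); Jaccard = |A∩B| / |A∪B|."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    na, nb = int(a.sum()), int(b.sum())
    if na == 0 and nb == 0:
        return OverlapResult(float("nan"), float("nan"))
    inter = int((a & b).sum())
    union = na + nb - inter
    return OverlapResult(2.0 * inter / (na + nb), inter / union)


def feature_label_correlation(
    table: pd.DataFrame, label_cols: list[str], predictors: list[str] | None = None
) -> pd.DataFrame:
    """Pearson r between each predictor and each binary label column.

    Constant predictors get r = 0 (flagged in ``attrs['constant']``).
    """
    if len(table) < 3:
        raise ValueError("need at least 3 lesions")
    if predictors is None:
        from ufrad.features import predictor_columns

        predictors = [c for c in predictor_columns(table) if c not in label_cols]
    out = np.zeros((len(predictors), len(label_cols)))
    constant = []
    for j, lab in enumerate(label_cols):
        y = table[lab].to_numpy(dtype=float)
        for i, col in enumerate(predictors):
            x = table[col].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                out[i, j] = 0.0
                if np.std(x) == 0 and col not in constant:
                    constant.append(col)
            else:
                out[i, j] = np.corrcoef(x, y)[0, 1]
    cm = pd.DataFrame(out, index=predictors, columns=label_cols)
    cm.attrs["constant"] = constant
    return cm
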