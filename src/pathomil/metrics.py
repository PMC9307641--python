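"""Evaluation metrics and analysis protocols.

Slide- and image-level classification is multilabel, scored with
micro-averaged accuracy over (sample, class) indicator cells and
support-weighted macro F1; patch-level classification is multiclass, scored
with Cohen's kappa.  Per-class precision/recall, one-vs-rest ROC/AUC, a
two-sided Wilcoxon rank-sum test (exact for small samples) and the
mislabeled-subset protocol (evaluating only cases whose automatic label
disagrees with ground truth) complete the toolkit.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn import metrics as skm

from .schema import CLASS_NAMES, N_CLASSES, frame_to_labels


class MetricsError(ValueError):
    pass


class UndefinedMetricError(MetricsError):
    """A metric is undefined for the given inputs (e.g. a degenerate class)."""


def _as_indicator(y) -> np.ndarray:
    arr = np.atleast_2d(np.asarray(y))
    if arr.size == 0:
        raise MetricsError("empty prediction table")
    if arr.shape[1] != N_CLASSES:
        raise MetricsError(f"expected {N_CLASSES} indicator columns, got {arr.shape[1]}")
    return arr.astype(int)


def micro_accuracy(gt, pred) -> float:
    """(TP + TN) / all cells, pooled over every (sample, class) indicator."""
    gt, pred = _as_indicator(gt), _as_indicator(pred)
    if gt.shape != pred.shape:
        raise MetricsError("ground truth and prediction shapes differ")
    return float(np.mean(gt == pred))


def exact_match_accuracy(gt, pred) -> float:
    """Per-sample all-classes-correct accuracy (logged, never the headline)."""
    gt, pred = _as_indicator(gt), _as_indicator(pred)
    return float(np.mean((gt == pred).all(axis=1)))


def per_class_prf(gt, pred) -> pd.DataFrame:
    """Per-class precision, recall, F1 and support (0 convention on 0/0)."""
    gt, pred = _as_indicator(gt), _as_indicator(pred)
    precision, recall, f1, support = skm.precision_recall_fscore_support(
        gt, pred, average=None, zero_division=0, labels=None
    )
    return pd.DataFrame(
        {
            "class": list(CLASS_NAMES),
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        }
    )


def weighted_f1(gt, pred) -> tuple[float, dict[str, float]]:
    """Support-weighted macro F1; zero-support classes carry zero weight.

    Raises when every class has zero support (no positive label anywhere).
    """
    table = per_class_prf(gt, pred)
    support = table["support"].to_numpy()
    if support.sum() == 0:
        raise UndefinedMetricError("weighted F1 undefined: all class supports are zero")
    value = float(np.average(table["f1"], weights=support))
    return value, dict(zip(table["class"], table["f1"].astype(float)))


def cohen_kappa(gt_classes, pred_classes) -> float:
    """Chance-corrected multiclass agreement kappa = (p_o - p_e) / (1 - p_e).

    Returns 1.0 for complete agreement even when chance agreement is 1.
    """
    gt = np.asarray(gt_classes, dtype=int)
    pred = np.asarray(pred_classes, dtype=int)
    if gt.size == 0:
        raise MetricsError("empty patch table")
    if np.array_equal(gt, pred):
        return 1.0
    return float(skm.cohen_kappa_score(gt, pred, labels=np.arange(N_CLASSES)))


def roc_auc(gt, scores, class_index: int) -> tuple[pd.DataFrame, float]:
    """One-vs-rest ROC curve (threshold sweep) and trapezoidal area.

    Raises UndefinedMetricError when the class has no positive or no
    negative samples instead of reporting a misleading 0.
    """
    gt = _as_indicator(gt)[:, class_index]
    scores = np.asarray(scores)
    if scores.ndim == 2:
        scores = scores[:, class_index]
    if gt.min() == gt.max():
        raise UndefinedMetricError(
            f"AUC undefined for class {CLASS_NAMES[class_index]}: "
            "needs at least one positive and one negative sample"
        )
    fpr, tpr, thresholds = skm.roc_curve(gt, scores)
    area = float(skm.auc(fpr, tpr))
    curve = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresholds})
    return curve, area


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum


def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


EXACT_LIMIT = 12


def rank_sum_test(sample_a, sample_b, method: str = "auto") -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    ``method='auto'`` uses the exact null (enumeration of rank assignments)
    when n_a + n_b <= 12 and a tie- and continuity-corrected normal
    approximation otherwise; 'exact' and 'normal' force a branch.  Returns
    (rank sum of sample a, p-value).
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MetricsError("both samples must be non-empty")
    if method not in {"auto", "exact", "normal"}:
        raise MetricsError(f"unknown method {method!r}")
    na, nb = len(a), len(b)
    n = na + nb
    ranks = _midranks(np.concatenate([a, b]))
    w = float(ranks[:na].sum())
    mean_w = na * (n + 1) / 2
    if method == "exact" or (method == "auto" and n <= EXACT_LIMIT):
        observed = abs(w - mean_w)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n), na):
            total += 1
            ws = ranks[list(combo)].sum()
            if abs(ws - mean_w) >= observed - 1e-12:
                count += 1
        return w, count / total
    # tie-corrected normal approximation with continuity correction
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var_w = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_w <= 0:
        return w, 1.0
    z = max(abs(w - mean_w) - 0.5, 0.0) / math.sqrt(var_w)
    return w, float(min(2 * norm.sf(z), 1.0))


# ---------------------------------------------------------------------------
# Mislabeled-subset protocol


@dataclass
class MislabelSet:
    case_ids: list[str]
    per_class_disagreement: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.case_ids)


def find_mislabeled(auto_labels: pd.DataFrame, gt_labels: pd.DataFrame) -> MislabelSet:
    """Cases whose automatic label disagrees with ground truth in >= 1 class.

    Both tables use the shared label CSV schema; the case_id sets must match.
    """
    auto_ids, auto = frame_to_labels(auto_labels)
    gt_ids, gt = frame_to_labels(gt_labels)
    if set(auto_ids) != set(gt_ids):
        raise MetricsError("auto and ground-truth tables cover different case_ids")
    order = {cid: i for i, cid in enumerate(gt_ids)}
    gt_aligned = gt[[order[c] for c in auto_ids]]
    diff = auto != gt_aligned
    mismatch_rows = diff.any(axis=1)
    per_class = {
        name: int(diff[:, i].sum()) for i, name in enumerate(CLASS_NAMES)
    }
    return MislabelSet(
        case_ids=[cid for cid, bad in zip(auto_ids, mismatch_rows) if bad],
        per_class_disagreement=per_class,
    )


# ---------------------------------------------------------------------------
# Aggregate report


@dataclass
class MetricsReport:
    micro_accuracy: float
    weighted_f1: float
    per_class: pd.DataFrame
    exact_match: float | None = None
    kappa: float | None = None
    auc: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        out = {
            "micro_accuracy": self.micro_accuracy,
            "weighted_f1": self.weighted_f1,
            "per_class": self.per_class.to_dict(orient="records"),
        }
        if self.exact_match is not None:
            out["exact_match_accuracy"] = self.exact_match
        if self.kappa is not None:
            out["kappa"] = self.kappa
        if self.auc:
            out["auc"] = self.auc
        return out


def evaluate_predictions(gt, pred, scores=None) -> MetricsReport:
    """Full multilabel report: micro accuracy, weighted F1, per-class P/R/F1,
    and per-class AUC where defined (degenerate classes are skipped)."""
    gt, pred = _as_indicator(gt), _as_indicator(pred)
    f1, _ = weighted_f1(gt, pred)
    auc: dict[str, float] = {}
    if scores is not None:
        for i, name in enumerate(CLASS_NAMES):
            try:
                _, auc[name] = roc_auc(gt, scores, i)
            except UndefinedMetricError:
                continue
    return MetricsReport(
        micro_accuracy=micro_accuracy(gt, pred),
        weighted_f1=f1,
        per_class=per_class_prf(gt, pred),
        exact_match=exact_match_accuracy(gt, pred),
        auc=auc,
    )
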