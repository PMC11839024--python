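"""Meta-analysis scoring of candidate organelle proteins.

Three localization metrics per protein — presence across independent
datasets, organelle-IP abundance, and interaction count with well-known
reference proteins — are each evaluated by ROC against a curated reference
list, combined by summation, and thresholded at a 10% false-positive rate
on the reference negatives. Proteins on an exclusion list (e.g. MitoCarta
membership) are never called.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.metrics import roc_curve

logger = logging.getLogger(__name__)

FP_TARGET = 0.10

METRIC_COLUMNS = ["dataset_presence", "ip_abundance", "ref_interaction_count"]


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    partial_auc: float  # area on FP axis in [0, fp_max]
    partial_auc_normalized: float
    fp_max: float
    degenerate: bool = False


def metric_roc(metric: np.ndarray | pd.Series, labels: np.ndarray | pd.Series,
               fp_max: float = FP_TARGET) -> RocResult:
    """ROC of a metric against reference labels, with partial AUC.

    The partial AUC integrates the ROC over false-positive rates in
    [0, ``fp_max``]; the normalized form divides by ``fp_max`` so a perfect
    separator scores 1.0 and chance scores ``fp_max``/2. A monotone
    (logistic) transform of the metric leaves the ROC unchanged, so the raw
    metric is used directly. A constant metric yields a degenerate
    chance-line ROC, flagged rather than raised.
    """
    metric = np.asarray(metric, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both label classes must be present")
    degenerate = np.unique(metric[~np.isnan(metric)]).size < 2
    if degenerate:
        fpr = np.array([0.0, 1.0])
        tpr = np.array([0.0, 1.0])
        thresholds = np.array([np.inf, metric[0]])
    else:
        fpr, tpr, thresholds = roc_curve(labels, metric, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    pauc = float(_partial_auc(fpr, tpr, fp_max))
    return RocResult(
        fpr=fpr, tpr=tpr, thresholds=thresholds, auc=auc,
        partial_auc=pauc, partial_auc_normalized=pauc / fp_max,
        fp_max=fp_max, degenerate=degenerate,
    )


def _partial_auc(fpr: np.ndarray, tpr: np.ndarray, fp_max: float) -> float:
    """Trapezoidal area under the ROC restricted to fpr ∈ [0, fp_max]."""
    tpr_at = np.interp(fp_max, fpr, tpr)
    mask = fpr < fp_max
    x = np.concatenate([fpr[mask], [fp_max]])
    y = np.concatenate([tpr[mask], [tpr_at]])
    return float(np.trapezoid(y, x))


def combine_scores(evidence: pd.DataFrame, standardize: bool = True) -> pd.Series:
    """Combine the three metrics by summation.

    With ``standardize`` (default) each metric is rank-normalized to [0, 1]
    before summing, making their units commensurable while preserving
    summation semantics; with ``standardize=False`` raw values are summed.
    Missing IP abundance is imputed as the observed minimum (absence ≈ not
    detected) and logged. The combined score is monotone non-decreasing in
    each metric.
    """
    metrics = evidence[METRIC_COLUMNS].copy()
    n_missing = int(metrics["ip_abundance"].isna().sum())
    if n_missing:
        floor = metrics["ip_abundance"].min()
        logger.info(
            "imputing %d missing ip_abundance values as observed minimum %.3f",
            n_missing, floor,
        )
        metrics["ip_abundance"] = metrics["ip_abundance"].fillna(floor)
    if standardize:
        for col in METRIC_COLUMNS:
            vals = metrics[col].to_numpy(dtype=float)
            ranks = rankdata(vals, method="average")
            metrics[col] = (ranks - 1) / max(len(vals) - 1, 1)
    return metrics.sum(axis=1).rename("combined_score")


def call_endosomal(
    combined_scores: pd.Series,
    is_reference: pd.Series,
    fp_target: float = FP_TARGET,
    exclusion: pd.Series | None = None,
) -> tuple[pd.DataFrame, float]:
    """Call organelle residency at a bounded false-positive rate.

    Negatives are proteins not on the curated reference list (no curated
    negative set exists, so non-reference status is the operational
    negative — an approximation). The threshold is the smallest score value
    for which the fraction of negatives at or above it is ≤ ``fp_target``;
    ties at the threshold are included (≥ comparison) and the constraint is
    re-verified, stepping to the next distinct score if violated. Excluded
    proteins are never called. Returns (call table, threshold).
    """
    if not 0.0 < fp_target < 1.0:
        raise ValueError("fp_target must be in (0, 1)")
    scores = combined_scores.astype(float)
    is_reference = is_reference.reindex(scores.index).astype(bool)
    neg = scores[~is_reference]
    if len(neg) == 0:
        raise ValueError("no reference-negative proteins; threshold undefined")
    candidates = np.sort(np.unique(scores.to_numpy()))
    threshold = None
    for t in candidates:  # ascending: first (smallest) t meeting the bound
        fp = float((neg >= t).mean())
        if fp <= fp_target:
            threshold = float(t)
            break
    if threshold is None:  # every score shared by too many negatives
        threshold = float(np.inf)
    excluded = (
        exclusion.reindex(scores.index).fillna(False).astype(bool)
        if exclusion is not None
        else pd.Series(False, index=scores.index)
    )
    predicted = (scores >= threshold) & ~excluded
    calls = pd.DataFrame(
        {
            "combined_score": scores,
            "is_reference": is_reference,
            "excluded": excluded,
            "predicted_endosomal": predicted,
            "threshold_used": threshold,
            "fp_rate_target": fp_target,
            "in_final_set": predicted | is_reference,
        }
    )
    return calls, threshold


def realized_fp_rate(calls: pd.DataFrame) -> float:
    """Fraction of reference negatives at or above the threshold used.

    Computed before exclusion-list removal, i.e. on the score threshold
    itself, so it is the quantity the 10% bound constrains.
    """
    neg = calls[~calls["is_reference"]]
    if len(neg) == 0:
        return float("nan")
    return float((neg["combined_score"] >= neg["threshold_used"]).mean())
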