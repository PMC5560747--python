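"""Scoring of predicted versus measured binding affinities.

Regression accuracy is summarized by the Pearson correlation and the root
mean squared error of predicted against measured pK_i values.  Because a
practitioner ultimately cares about discriminating interacting from
non-interacting pairs, predictions are additionally scored by a ROC-AUC
sweep: the measured affinities are binarized at a series of interaction
thresholds (typically 11 values spanning pK 6-8, or a finer 21-value sweep
at step 0.1), an AUC is computed at each threshold, and the mean over valid
thresholds is reported.  Degenerate thresholds that leave a single class are
skipped and listed rather than counted as 0.5.

A hypergeometric upper-tail test quantifies off-target enrichment: given a
kinase panel of known size, an assumed number of true targets, and a set of
experimentally tested predictions, it gives the probability of observing at
least the attained number of hits by chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln
from sklearn.metrics import roc_auc_score

__all__ = [
    "EvaluationReport",
    "pearson",
    "rmse",
    "roc_auc_sweep",
    "hypergeometric_enrichment",
    "apply_floor",
    "evaluate_predictions",
]


@dataclass
class EvaluationReport:
    """Bundle of regression and classification accuracy statistics."""

    pearson_r: float
    rmse: float
    auc_by_threshold: dict[float, float]
    mean_auc: float
    n: int
    skipped_thresholds: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "pearson_r": self.pearson_r,
            "rmse": self.rmse,
            "auc_by_threshold": {str(k): v for k, v in self.auc_by_threshold.items()},
            "mean_auc": self.mean_auc,
            "n": self.n,
            "skipped_thresholds": list(self.skipped_thresholds),
        }


def pearson(x, y) -> float:
    """Pearson product-moment correlation of two paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("inputs must be equal-length vectors")
    if x.size < 2:
        raise ValueError("need at least two pairs")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float((xc @ yc) / denom)


def rmse(x, y) -> float:
    """Root mean squared error between paired vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be equal-length vectors")
    return float(np.sqrt(np.mean((x - y) ** 2)))


def roc_auc_sweep(
    measured, predicted, thresholds
) -> tuple[dict[float, float], float, list[float]]:
    """AUC at each interaction threshold.

    A pair is a positive when its measured affinity is >= the threshold
    (boundary included).  AUC uses the rank statistic with tied predictions
    averaged.  Thresholds yielding a single class are skipped and returned
    in the third element.

    Returns ``(auc_by_threshold, mean_auc, skipped)``.
    """
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape:
        raise ValueError("inputs must be equal-length vectors")
    aucs: dict[float, float] = {}
    skipped: list[float] = []
    for thr in thresholds:
        labels = measured >= thr
        if labels.all() or not labels.any():
            skipped.append(float(thr))
            continue
        aucs[float(thr)] = float(roc_auc_score(labels, predicted))
    if skipped:
        warnings.warn(
            f"skipped single-class thresholds: {skipped}", stacklevel=2
        )
    mean_auc = float(np.mean(list(aucs.values()))) if aucs else float("nan")
    return aucs, mean_auc, skipped


def hypergeometric_enrichment(
    population: int, true_targets: int, tested: int, hits: int
) -> float:
    """Upper-tail hypergeometric probability P(X >= hits).

    X counts true targets among ``tested`` draws without replacement from a
    ``population`` containing ``true_targets`` true targets.  Computed by
    exact summation of log-probabilities (log-gamma binomials).
    """
    if not (0 <= hits <= tested <= population):
        raise ValueError("require 0 <= hits <= tested <= population")
    if not (0 <= true_targets <= population):
        raise ValueError("require 0 <= true_targets <= population")

    def log_comb(n: int, k: int) -> float:
        return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)

    upper = min(tested, true_targets)
    if hits > upper:
        return 0.0
    log_denom = log_comb(population, tested)
    log_terms = [
        log_comb(true_targets, k)
        + log_comb(population - true_targets, tested - k)
        - log_denom
        for k in range(hits, upper + 1)
        if tested - k <= population - true_targets
    ]
    if not log_terms:
        return 0.0
    m = max(log_terms)
    return float(min(1.0, np.exp(m) * np.sum(np.exp(np.array(log_terms) - m))))


def apply_floor(measured, floor_value: float, no_interaction_mask=None) -> np.ndarray:
    """Replace undetected/no-interaction measurements by a floor value.

    In an assay with a highest tested concentration, pairs showing no clear
    interaction get the pIC50 corresponding to that concentration (e.g. 4.9
    for a 12,500 nM ceiling) before scoring.  When ``no_interaction_mask``
    is None, non-finite entries are treated as undetected.
    """
    measured = np.asarray(measured, dtype=float).copy()
    if no_interaction_mask is None:
        mask = ~np.isfinite(measured)
    else:
        mask = np.asarray(no_interaction_mask, dtype=bool)
        if mask.shape != measured.shape:
            raise ValueError("mask shape must match measurements")
    measured[mask] = floor_value
    return measured


def evaluate_predictions(
    measured,
    predicted,
    thresholds=None,
    floor_value: float | None = None,
    no_interaction_mask=None,
) -> EvaluationReport:
    """Full evaluation: optional assay floor, then Pearson, RMSE, and the
    threshold AUC sweep (default 11 thresholds spanning pK 6-8)."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if floor_value is not None:
        measured = apply_floor(measured, floor_value, no_interaction_mask)
    if thresholds is None:
        thresholds = np.linspace(6.0, 8.0, 11)
    aucs, mean_auc, skipped = roc_auc_sweep(measured, predicted, thresholds)
    return EvaluationReport(
        pearson_r=pearson(measured, predicted),
        rmse=rmse(measured, predicted),
        auc_by_threshold=aucs,
        mean_auc=mean_auc,
        n=len(measured),
        skipped_thresholds=skipped,
    )
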