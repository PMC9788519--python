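"""ROC analysis of the predictive score, Youden-optimal cutoff, and
permutation significance of the cross-validated metrics."""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .errors import DataError
from .oplsda import cross_validate

logger = logging.getLogger(__name__)

__all__ = ["ROCCurve", "PermutationResult", "roc_auc", "youden_cutoff",
           "permutation_test"]


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    class_mean_midpoint: float
    youden_cutoff: float | None = None
    youden_j: float | None = None

    @property
    def sens_at_cutoff(self) -> float:
        i = int(np.argmin(np.abs(self.thresholds - self.youden_cutoff)))
        return float(self.sensitivity[i])

    @property
    def spec_at_cutoff(self) -> float:
        i = int(np.argmin(np.abs(self.thresholds - self.youden_cutoff)))
        return float(self.specificity[i])


@dataclass
class PermutationResult:
    metric: str
    observed: float
    permuted: np.ndarray
    n_runs: int

    @property
    def p_value(self) -> float:
        # add-one rule: never exactly zero
        return (1 + int((self.permuted >= self.observed).sum())) / (self.n_runs + 1)


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve of case-positive scores.

    AUC by the rank (Mann-Whitney) formulation with half-credit for ties;
    curve thresholds at midpoints between consecutive observed scores, with
    a sample classified positive when its score exceeds the threshold.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    case = y == np.max(y)
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise DataError("both classes must be present for ROC analysis")
    r = rankdata(scores)
    auc = (r[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)

    uniq = np.unique(scores)
    mids = (uniq[:-1] + uniq[1:]) / 2 if len(uniq) > 1 else np.array([])
    span = (uniq[-1] - uniq[0]) or 1.0
    thresholds = np.concatenate([[uniq[0] - 0.05 * span], mids,
                                 [uniq[-1] + 0.05 * span]])
    sens = np.array([(scores[case] > t).mean() for t in thresholds])
    spec = np.array([(scores[~case] <= t).mean() for t in thresholds])
    curve = ROCCurve(thresholds=thresholds, sensitivity=sens, specificity=spec,
                     auc=float(auc),
                     class_mean_midpoint=float((scores[case].mean()
                                                + scores[~case].mean()) / 2))
    curve.youden_cutoff = youden_cutoff(curve)
    j = curve.sensitivity + curve.specificity - 1
    curve.youden_j = float(j.max())
    return curve


def youden_cutoff(roc: ROCCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1.

    Ties (within 1e-12) are resolved to the threshold nearest the midpoint
    of the two class means, which fixes a unique cutoff when the classes
    are perfectly separated.
    """
    j = roc.sensitivity + roc.specificity - 1
    best = j.max()
    ties = np.flatnonzero(j >= best - 1e-12)
    if len(ties) > 1:
        logger.debug("Youden tie over %d thresholds; taking nearest class-mean midpoint",
                     len(ties))
    pick = ties[np.argmin(np.abs(roc.thresholds[ties] - roc.class_mean_midpoint))]
    return float(roc.thresholds[pick])


def _metric_value(scores: np.ndarray, y: np.ndarray, metric: str) -> float:
    curve = roc_auc(scores, y)
    if metric == "auc":
        return curve.auc
    if metric == "sensitivity":
        return curve.sens_at_cutoff
    if metric == "specificity":
        return curve.spec_at_cutoff
    raise DataError(f"unknown metric {metric!r}; use auc/sensitivity/specificity")


def permutation_test(X, y, metric: str = "auc", n_runs: int = 100,
                     seed: int = 0, folds: int = 5, repeats: int = 10
                     ) -> PermutationResult:
    """Permutation significance of a cross-validated metric.

    Each run permutes the class labels, reruns the full cross-validation,
    and records the metric on the aggregated out-of-fold scores.  The
    p-value uses the add-one rule (1 + #{permuted >= observed})/(runs + 1).
    """
    if n_runs < 1:
        raise DataError(f"n_runs must be >= 1, got {n_runs}")
    if metric not in ("auc", "sensitivity", "specificity"):
        raise DataError(f"unknown metric {metric!r}")
    y = np.asarray(y)
    cv = cross_validate(X, y, folds=folds, repeats=repeats, seed=seed)
    observed = _metric_value(cv.aggregate, y, metric)
    rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, 977])
    permuted = np.empty(n_runs)
    for i in range(n_runs):
        yp = rng.permutation(y)
        cvp = cross_validate(X, yp, folds=folds, repeats=repeats,
                             seed=int(rng.integers(2 ** 31)))
        permuted[i] = _metric_value(cvp.aggregate, yp, metric)
    return PermutationResult(metric=metric, observed=float(observed),
                             permuted=permuted, n_runs=n_runs)
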