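"""Phenoreversion quantification.

The D statistic (distance of a projected sample to the healthy-control
metabotype), per-subject linear recovery-day estimation, maximum-likelihood
fitting of the recovery-day distribution as a generalized extreme value
(GEV) law, recovered-fraction time courses over the follow-up day bins,
and severity / age sub-models.

GEV sign convention follows the R package ``evd``: positive shape means a
heavy right tail (the scipy ``genextreme`` shape is its negative).
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gamma as gamma_fn

from .errors import DataError
from .oplsda import OPLSModel

logger = logging.getLogger(__name__)

__all__ = ["RecoveryConfig", "RecoveryEstimate", "GEVFit", "DEFAULT_DAY_BINS",
           "distance_to_recovery", "estimate_recovery_days",
           "estimate_all_subjects", "fit_gev", "recovered_fraction",
           "subgroup_models"]

#: Follow-up day bins of the study design; ">60" capped at 120 days.
DEFAULT_DAY_BINS = [(0, 7), (7, 14), (14, 30), (30, 60), (60, 120)]


@dataclass
class RecoveryConfig:
    min_followup_days: int = 14
    #: 2 = acute + at least one follow-up; 3 mirrors the stricter
    #: three-or-more-samples eligibility mode
    min_samples_for_subject_fit: int = 2
    #: how the offset constant k of the D statistic is fixed
    k_offset_rule: str = "zero-at-hc-mean"
    age_split: float = 65.0

    def __post_init__(self) -> None:
        if self.min_followup_days < 0:
            raise DataError("min_followup_days must be >= 0")
        if self.age_split <= 0:
            raise DataError("age_split must be > 0")


@dataclass
class RecoveryEstimate:
    subject_id: str
    slope: float
    intercept: float
    recovery_days: float
    n_samples: int
    valid: bool
    exclusion_reason: str | None = None


@dataclass
class GEVFit:
    """Three-parameter GEV (location/scale/shape, evd convention)."""

    location: float
    scale: float
    shape: float
    loglik: float
    n: int
    converged: bool

    def mode(self) -> float:
        """Day of maximum density."""
        xi = self.shape
        if abs(xi) < 1e-12:
            return self.location
        return self.location + self.scale / xi * ((1 + xi) ** (-xi) - 1)

    def quantile(self, q: float) -> float:
        return float(sps.genextreme.ppf(q, -self.shape,
                                        loc=self.location, scale=self.scale))

    def cdf(self, x) -> np.ndarray:
        return sps.genextreme.cdf(x, -self.shape, loc=self.location,
                                  scale=self.scale)


def distance_to_recovery(scores: pd.DataFrame, model: OPLSModel,
                         cfg: RecoveryConfig | None = None) -> pd.DataFrame:
    """Per-sample D statistic: D = t_pred - cutoff + k with
    k = cutoff - hc_mean, i.e. D = t_pred - hc_mean, zero exactly at the
    healthy-control mean score.  A sample counts as recovered when its
    score is on the healthy side of the Youden cutoff (D <= cutoff - hc_mean).
    """
    cfg = cfg or RecoveryConfig()
    if model.cutoff_tpred is None:
        raise DataError("model has no decision cutoff; run the ROC/Youden "
                        "evaluation first")
    k = model.cutoff_tpred - model.hc_mean_tpred
    out = scores.copy()
    out["d_value"] = out["t_pred"] - model.hc_mean_tpred
    out["k"] = k
    out["recovered"] = out["t_pred"] <= model.cutoff_tpred
    return out


def estimate_recovery_days(subject_scores: pd.DataFrame, hc_mean: float,
                           cfg: RecoveryConfig | None = None) -> RecoveryEstimate:
    """Least-squares line of t_pred on day for one subject; the recovery day
    is where the line reaches the healthy-control mean score.

    Eligibility: an acute (day 0) sample, at least one follow-up at or past
    ``min_followup_days``, and at least ``min_samples_for_subject_fit``
    samples in total.  Non-recovering trajectories (non-negative slope, or a
    crossing in the past) are returned invalid rather than dropped silently.
    """
    cfg = cfg or RecoveryConfig()
    sid = str(subject_scores["subject_id"].iloc[0]) if "subject_id" in subject_scores else "?"
    days = subject_scores["day"].to_numpy(dtype=float)
    t = subject_scores["t_pred"].to_numpy(dtype=float)
    n = len(days)
    eligible = ((days == 0).any()
                and (days >= cfg.min_followup_days).any()
                and n >= cfg.min_samples_for_subject_fit
                and len(np.unique(days)) >= 2)
    if not eligible:
        return RecoveryEstimate(sid, np.nan, np.nan, np.nan, n,
                                valid=False, exclusion_reason="eligibility")
    slope, intercept = np.polyfit(days, t, 1)
    if slope >= 0:
        return RecoveryEstimate(sid, float(slope), float(intercept), np.nan, n,
                                valid=False, exclusion_reason="non-recovering trajectory")
    rec = (hc_mean - intercept) / slope
    if not (np.isfinite(rec) and rec > 0):
        return RecoveryEstimate(sid, float(slope), float(intercept), float(rec), n,
                                valid=False, exclusion_reason="non-recovering trajectory")
    return RecoveryEstimate(sid, float(slope), float(intercept), float(rec), n,
                            valid=True)


def estimate_all_subjects(scores: pd.DataFrame, hc_mean: float,
                          cfg: RecoveryConfig | None = None
                          ) -> list[RecoveryEstimate]:
    """Apply the per-subject estimator to a long score table
    (columns subject_id, day, t_pred)."""
    return [estimate_recovery_days(grp, hc_mean, cfg)
            for _, grp in scores.groupby("subject_id", sort=True)]


def _pwm_init(x: np.ndarray) -> tuple[float, float, float]:
    """Probability-weighted-moment starting values (Hosking's estimators)."""
    xs = np.sort(x)
    n = len(xs)
    i = np.arange(n)
    b0 = xs.mean()
    b1 = (i / (n - 1) * xs).mean()
    b2 = (i * (i - 1) / ((n - 1) * (n - 2)) * xs).mean()
    l1, l2 = b0, 2 * b1 - b0
    t3 = (6 * b2 - 6 * b1 + b0) / l2 if l2 > 0 else 0.0
    z = 2.0 / (3.0 + t3) - math.log(2) / math.log(3)
    k = 7.8590 * z + 2.9554 * z * z   # Hosking shape; equals scipy's c
    if abs(k) < 1e-6:
        scale = l2 / math.log(2)
        loc = l1 - scale * 0.5772156649
        return 0.0, loc, max(scale, 1e-8)
    g = gamma_fn(1 + k)
    scale = l2 * k / ((1 - 2.0 ** (-k)) * g)
    loc = l1 - scale * (1 - g) / k
    return k, loc, max(scale, 1e-8)


def fit_gev(recovery_days) -> GEVFit:
    """Maximum-likelihood GEV fit of a sample of recovery days.

    Initialized from probability-weighted moments; the support constraint
    1 + shape*(x - location)/scale > 0 is verified for every observation
    and the converged flag is honest (no silent fallback).
    """
    x = np.asarray(recovery_days, dtype=float)
    x = x[np.isfinite(x)]
    if len(x) < 10:
        raise DataError(f"need >= 10 recovery-day values to fit a GEV, have {len(x)}")
    c0, loc0, scale0 = _pwm_init(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            c, loc, scale = sps.genextreme.fit(x, c0, loc=loc0, scale=scale0)
        except Exception as exc:  # optimizer failure
            logger.warning("GEV fit did not converge: %s", exc)
            return GEVFit(loc0, scale0, -c0, np.nan, len(x), converged=False)
        loglik = float(np.sum(sps.genextreme.logpdf(x, c, loc=loc, scale=scale)))
    shape = -c  # evd convention
    support_ok = bool(np.all(1 + shape * (x - loc) / scale > 0)) if abs(shape) > 1e-12 else True
    converged = bool(np.isfinite(loglik) and scale > 0 and support_ok)
    if not converged:
        logger.warning("GEV fit rejected: loglik=%s scale=%s support_ok=%s",
                       loglik, scale, support_ok)
    return GEVFit(float(loc), float(scale), float(shape), loglik, len(x), converged)


def _bin_label(lo: float, hi: float) -> str:
    return f"({lo},{hi}]"


def recovered_fraction(d_stats: pd.DataFrame,
                       bins: list[tuple[float, float]] | None = None
                       ) -> dict[str, float]:
    """Fraction of samples flagged recovered per follow-up day bin.

    Bins are half-open (lo, hi]; day 0 counts into the first bin when that
    bin starts at 0 (the acute sample is part of the earliest window).
    Bins holding no samples are omitted rather than reported as zero.
    """
    bins = bins if bins is not None else DEFAULT_DAY_BINS
    if "day" not in d_stats.columns:
        raise DataError("d_stats needs a 'day' column")
    out: dict[str, float] = {}
    days = d_stats["day"].to_numpy(dtype=float)
    rec = d_stats["recovered"].to_numpy(dtype=bool)
    for lo, hi in bins:
        mask = (days > lo) & (days <= hi)
        if lo == 0:
            mask |= days == 0
        if mask.any():
            out[_bin_label(lo, hi)] = float(rec[mask].mean())
    return out


def subgroup_models(estimates: list[RecoveryEstimate],
                    groups: dict[str, str], min_n: int = 10
                    ) -> dict[str, GEVFit]:
    """Independent GEV fits of the valid recovery days per subject group
    (e.g. severity class, or age above/below the configured split).
    Undersized groups are skipped with a warning."""
    frame = pd.DataFrame([{"subject_id": e.subject_id, "rec": e.recovery_days,
                           "valid": e.valid} for e in estimates])
    frame["group"] = frame["subject_id"].map(groups)
    fits: dict[str, GEVFit] = {}
    for label, grp in frame.dropna(subset=["group"]).groupby("group"):
        vals = grp.loc[grp["valid"], "rec"].to_numpy()
        if len(vals) < min_n:
            logger.warning("subgroup %r has only %d valid estimates; skipped",
                           label, len(vals))
            continue
        fits[str(label)] = fit_gev(vals)
    return fits
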