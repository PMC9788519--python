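"""Cytokine / chemokine analysis.

Group comparison per marker (binary-log fold change of group means plus a
Mann-Whitney-Wilcoxon test), per-subject linear decay of an elevated marker
from day 8 onward, and the correlation between the inflammatory and
metabolic recovery times (the MCP-1 coupling).
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.stats import rankdata

from .errors import DataError
from .recovery import RecoveryEstimate

__all__ = ["FoldChangeResult", "DecayEstimate", "CorrelationResult",
           "mannwhitney_p", "fold_change_analysis", "marker_decay",
           "correlate_recovery"]


@dataclass
class FoldChangeResult:
    marker: str
    log2_fc: float
    p_mw: float
    significant: bool
    n_case: int
    n_control: int
    note: str | None = None


@dataclass
class DecayEstimate:
    marker: str
    subject_id: str
    slope: float
    intercept: float
    half_recovery_day: float
    valid: bool
    n_samples: int = 0


@dataclass
class CorrelationResult:
    r: float
    p: float
    slope: float
    intercept: float
    n: int
    band: pd.DataFrame  # x, fit, lo, hi (95% confidence band of the mean)


# -- Mann-Whitney ----------------------------------------------------------

_EXACT_MAX = 10  # per group; enumeration is C(20,10) = 184k assignments


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    pooled = np.concatenate([x, y])
    r = rankdata(pooled)  # midranks, so ties get half-credit
    n1 = len(x)
    return float(r[:n1].sum() - n1 * (n1 + 1) / 2)


def _exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating every group assignment.

    Valid with ties (which the usual recursion-based exact method is not):
    the permutation distribution of U over all C(n1+n2, n1) relabelings.
    Two-sided rule: 2 * min(P(U <= u), P(U >= u)), capped at 1, matching
    the tie-free exact convention.
    """
    pooled = np.concatenate([x, y])
    r = rankdata(pooled)
    n1, n = len(x), len(pooled)
    offset = n1 * (n1 + 1) / 2
    u_obs = round(float(r[:len(x)].sum() - offset), 8)
    total = comb(n, n1)
    le = ge = 0
    for idx in combinations(range(n), n1):
        u = round(float(r[list(idx)].sum() - offset), 8)
        if u <= u_obs:
            le += 1
        if u >= u_obs:
            ge += 1
    return min(1.0, 2.0 * min(le, ge) / total)


def mannwhitney_p(x, y) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact by full enumeration when both groups have <= 10 observations
    (correct under ties); scipy's exact method for tie-free groups up to
    20; otherwise the tie-corrected normal approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise DataError("both groups must be non-empty")
    if max(len(x), len(y)) <= _EXACT_MAX:
        return _exact_p(x, y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not has_ties and max(len(x), len(y)) <= 20:
        return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="exact").pvalue)
    return float(sps.mannwhitneyu(x, y, alternative="two-sided",
                                  method="asymptotic").pvalue)


# -- group comparison ------------------------------------------------------

def fold_change_analysis(panel: pd.DataFrame, case_ids, control_ids,
                         alpha: float = 0.05) -> list[FoldChangeResult]:
    """Per-marker binary-log fold change (case mean over control mean) and
    Mann-Whitney significance at the given level (raw p, no correction
    across the 13 markers)."""
    case_ids, control_ids = set(case_ids), set(control_ids)
    results = []
    for marker, grp in panel.groupby("marker", sort=True):
        cx = grp.loc[grp["sample_id"].isin(case_ids), "level"].to_numpy(dtype=float)
        cy = grp.loc[grp["sample_id"].isin(control_ids), "level"].to_numpy(dtype=float)
        if len(cx) < 3 or len(cy) < 3:
            raise DataError(f"marker {marker!r}: need >= 3 samples per group "
                            f"(case {len(cx)}, control {len(cy)})")
        if cy.mean() <= 0:
            results.append(FoldChangeResult(str(marker), np.nan, 1.0, False,
                                            len(cx), len(cy),
                                            note="zero control mean"))
            continue
        p = mannwhitney_p(cx, cy)
        results.append(FoldChangeResult(
            marker=str(marker),
            log2_fc=float(np.log2(cx.mean() / cy.mean())),
            p_mw=p,
            significant=bool(p < alpha),
            n_case=len(cx), n_control=len(cy)))
    return results


# -- decay and coupling ----------------------------------------------------

def marker_decay(series: pd.DataFrame, healthy_mean: float,
                 acute_mean: float | None = None,
                 decay_from_day: float = 8.0) -> DecayEstimate:
    """Linear decay of one subject's marker from day 8 onward.

    The half-recovery day is where the fitted line crosses the midpoint
    between the acute mean and the healthy mean.  With no acute mean given
    it is taken from the subject's own samples at or before day 8.
    """
    marker = str(series["marker"].iloc[0]) if "marker" in series else "?"
    sid = str(series["subject_id"].iloc[0]) if "subject_id" in series else "?"
    late = series.loc[series["day"] >= decay_from_day]
    if len(late) < 2 or late["day"].nunique() < 2:
        return DecayEstimate(marker, sid, np.nan, np.nan, np.nan,
                             valid=False, n_samples=len(late))
    if acute_mean is None:
        early = series.loc[series["day"] <= decay_from_day, "level"]
        acute_mean = float(early.mean()) if len(early) else float(late["level"].max())
    slope, intercept = np.polyfit(late["day"].to_numpy(dtype=float),
                                  late["level"].to_numpy(dtype=float), 1)
    midpoint = (acute_mean + healthy_mean) / 2.0
    half_day = (midpoint - intercept) / slope if slope != 0 else np.inf
    valid = bool(slope < 0 and np.isfinite(half_day) and half_day > decay_from_day)
    return DecayEstimate(marker, sid, float(slope), float(intercept),
                         float(half_day), valid=valid, n_samples=len(late))


def correlate_recovery(decays: list[DecayEstimate],
                       estimates: list[RecoveryEstimate],
                       use: str = "half_recovery_day") -> CorrelationResult:
    """Pearson correlation between a marker's inflammatory recovery and the
    metabolic recovery days across subjects, with the least-squares line
    and its 95% confidence band for reporting.

    ``use`` selects the inflammatory quantity: the per-subject half-recovery
    day (default) or the decay slope.
    """
    if use not in ("half_recovery_day", "slope"):
        raise DataError(f"unknown decay quantity {use!r}")
    dec = {d.subject_id: getattr(d, use) for d in decays if d.valid}
    met = {e.subject_id: e.recovery_days for e in estimates if e.valid}
    common = sorted(set(dec) & set(met))
    if len(common) < 5:
        raise DataError(f"need >= 5 subjects with both recovery quantities, "
                        f"have {len(common)}")
    x = np.array([dec[s] for s in common])
    y = np.array([met[s] for s in common])
    if np.std(x) == 0 or np.std(y) == 0:
        raise DataError("degenerate (constant) recovery quantities")
    r, p = sps.pearsonr(x, y)
    slope, intercept = np.polyfit(x, y, 1)

    n = len(x)
    yhat = intercept + slope * x
    s2 = float(((y - yhat) ** 2).sum() / max(n - 2, 1))
    grid = np.linspace(x.min(), x.max(), 50)
    sxx = float(((x - x.mean()) ** 2).sum())
    se = np.sqrt(s2 * (1 / n + (grid - x.mean()) ** 2 / sxx))
    tq = sps.t.ppf(0.975, max(n - 2, 1))
    fit = intercept + slope * grid
    band = pd.DataFrame({"x": grid, "fit": fit,
                         "lo": fit - tq * se, "hi": fit + tq * se})
    return CorrelationResult(float(r), float(p), float(slope),
                             float(intercept), n, band)
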