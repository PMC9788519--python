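"""Turn raw tables and spectra into analysis-ready matrices.

Four responsibilities: label samples with days since COVID-19 onset,
integrate 1D spectra into fixed 0.03-ppm buckets (with the GlycA / GlycB /
SPC bins picked out), discard isolated samples with DBSCAN, and
log-transform + autoscale the quantified variables.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .errors import ConfigError, DataError
from .sampletable import SampleTable
from .synthgen import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "QCConfig", "BinGrid", "ScalingStats",
    "assign_days_since_covid", "bin_spectrum", "extract_glyc_spc",
    "qc_filter_dbscan", "log_standardize",
]


@dataclass
class QCConfig:
    """DBSCAN sample-filtering parameters (standardized Euclidean space)."""

    min_pts: int = 5
    eps: float = 20.0
    k_for_knn_plot: int = 5

    def __post_init__(self) -> None:
        if self.min_pts < 2:
            raise ConfigError(f"min_pts must be >= 2, got {self.min_pts}")
        if self.eps <= 0:
            raise ConfigError(f"eps must be > 0, got {self.eps}")


@dataclass
class BinGrid:
    """Fixed-width bucket grid over the 1H chemical-shift axis.

    Buckets are half-open ``[start + k*width, start + (k+1)*width)``; the
    residual-water region contributes neither to the buckets nor to the
    normalizing total.  The named inflammation bins are resolved to the
    bucket whose *center* is nearest the nominal shift (ties to the
    lower-ppm bucket, logged), since the nominal centers do not align
    exactly with a 0.5-anchored 0.03-ppm grid.
    """

    start: float = 0.5
    end: float = 9.5
    width: float = 0.03
    excluded: tuple[float, float] = (4.7, 5.0)
    named_bins: dict[str, float] = field(
        default_factory=lambda: {"GlycA": 2.06, "GlycB": 2.09, "SPC": 3.23})

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ConfigError(f"bin width must be > 0, got {self.width}")
        lo, hi = self.excluded
        if not (self.start <= lo <= hi <= self.end):
            raise ConfigError("excluded region must lie inside [start, end]")

    @property
    def n_bins(self) -> int:
        return int(math.floor((self.end - self.start) / self.width))

    def edges(self) -> np.ndarray:
        return self.start + self.width * np.arange(self.n_bins + 1)

    def centers(self) -> np.ndarray:
        return self.start + self.width * (np.arange(self.n_bins) + 0.5)

    def excluded_mask(self) -> np.ndarray:
        """Bins whose interval overlaps the excluded region."""
        e = self.edges()
        lo, hi = self.excluded
        return (e[:-1] < hi) & (e[1:] > lo)

    def named_bin_index(self, name: str) -> int:
        target = self.named_bins[name]
        centers = self.centers()
        d = np.abs(centers - target)
        best = float(d.min())
        ties = np.flatnonzero(np.isclose(d, best, rtol=0, atol=1e-12))
        if len(ties) > 1:
            logger.info("named bin %r at %.3f ppm ties between centers %s; "
                        "taking the lower-ppm bin", name, target,
                        np.round(centers[ties], 4).tolist())
        return int(ties[0])


def assign_days_since_covid(samples: SampleTable) -> SampleTable:
    """Attach ``days_since_covid`` and ``acute`` columns.

    Non-hospitalized recovered (NHR) rows: collection − covid report date.
    Hospitalized rows (AC/RE): the subject's earliest sample is time zero
    and flagged acute if collected within 7 days of hospitalization, and
    later samples are counted from it; otherwise every sample is counted
    from the hospitalization date and nothing is flagged acute.
    Rows missing the date their cohort requires are excluded (logged).
    HC rows keep a null day label.
    """
    df = samples.data.copy()
    df["days_since_covid"] = np.nan
    df["acute"] = False
    drop = np.zeros(len(df), dtype=bool)

    nhr = df["cohort"] == "NHR"
    bad = nhr & df["covid_report_date"].isna()
    if bad.any():
        logger.warning("excluding %d NHR rows without covid_report_date", bad.sum())
        drop |= bad.to_numpy()
    ok = nhr & ~bad
    df.loc[ok, "days_since_covid"] = (
        df.loc[ok, "collection_date"] - df.loc[ok, "covid_report_date"]
    ).dt.days

    hosp = df["cohort"].isin(["AC", "RE"])
    bad = hosp & df["hospitalization_date"].isna()
    if bad.any():
        logger.warning("excluding %d hospitalized rows without hospitalization_date",
                       bad.sum())
        drop |= bad.to_numpy()
    for _sid, grp in df.loc[hosp & ~bad].groupby("subject_id", sort=False):
        first_idx = grp["collection_date"].idxmin()
        delta0 = (grp.loc[first_idx, "collection_date"]
                  - grp.loc[first_idx, "hospitalization_date"]).days
        if 0 <= delta0 <= 7:
            t0 = grp.loc[first_idx, "collection_date"]
            df.loc[grp.index, "days_since_covid"] = (
                grp["collection_date"] - t0).dt.days
            df.loc[first_idx, "acute"] = True
        else:
            df.loc[grp.index, "days_since_covid"] = (
                grp["collection_date"] - grp["hospitalization_date"]).dt.days
    out = df.loc[~drop].reset_index(drop=True)
    return SampleTable(out, list(samples.variables))


def bin_spectrum(spec: Spectrum, grid: BinGrid | None = None) -> np.ndarray:
    """Integrate a spectrum into the bucket grid, total-intensity normalized.

    Points inside the excluded (residual water) region contribute to neither
    the buckets nor the normalizing total; the returned values sum to 1.
    """
    grid = grid or BinGrid()
    ppm, inten = spec.ppm, spec.intensity
    if ppm[0] > grid.start or ppm[-1] < grid.end - grid.width:
        raise DataError("spectrum does not cover the bin grid range")
    k = np.floor((ppm - grid.start) / grid.width).astype(int)
    lo, hi = grid.excluded
    keep = (k >= 0) & (k < grid.n_bins) & ~((ppm >= lo) & (ppm < hi))
    total = inten[keep].sum()
    if total <= 0:
        raise DataError("all-zero spectrum outside the excluded region; "
                        "total-intensity normalization is undefined")
    values = np.bincount(k[keep], weights=inten[keep], minlength=grid.n_bins)
    return values / total


def extract_glyc_spc(bins: np.ndarray, grid: BinGrid | None = None
                     ) -> tuple[float, float, float]:
    """(GlycA, GlycB, SPC) bucket values from a binned spectrum."""
    grid = grid or BinGrid()
    if len(bins) != grid.n_bins:
        raise DataError(f"expected {grid.n_bins} bins, got {len(bins)}")
    idx = [grid.named_bin_index(n) for n in ("GlycA", "GlycB", "SPC")]
    if len(set(idx)) != 3:
        raise DataError("GlycA/GlycB/SPC bins are not distinct on this grid")
    return tuple(float(bins[i]) for i in idx)


def _standardize_raw(values: pd.DataFrame) -> np.ndarray:
    x = values.to_numpy(dtype=float)
    mean = x.mean(axis=0)
    sd = x.std(axis=0)  # population SD, matching the clustering convention
    keep = sd > 0
    if not keep.all():
        logger.warning("dropping %d constant variables from QC clustering",
                       (~keep).sum())
    return (x[:, keep] - mean[keep]) / sd[keep]


def qc_filter_dbscan(samples: SampleTable, qc: QCConfig | None = None
                     ) -> tuple[SampleTable, list[str]]:
    """Remove isolated samples: DBSCAN noise points in standardized space.

    All quantified variables are centered and unit-variance scaled, DBSCAN
    is run with the configured (eps, min_pts) on Euclidean distance, and
    samples assigned to no cluster are discarded (members of *any* cluster
    are kept).
    """
    qc = qc or QCConfig()
    if len(samples) < qc.min_pts:
        raise DataError(f"need at least min_pts={qc.min_pts} samples, have {len(samples)}")
    z = _standardize_raw(samples.values_matrix())
    labels = DBSCAN(eps=qc.eps, min_samples=qc.min_pts).fit_predict(z)
    noise = labels == -1
    discarded = samples.data.loc[noise, "sample_id"].tolist()
    logger.info("DBSCAN QC (eps=%g, min_pts=%d): discarded %d of %d samples",
                qc.eps, qc.min_pts, len(discarded), len(samples))
    kept = samples.subset(~noise)
    return kept, discarded


def knn_distances(samples: SampleTable, k: int = 5) -> np.ndarray:
    """Sorted k-NN distances in standardized space (the eps-selection plot)."""
    z = _standardize_raw(samples.values_matrix())
    from sklearn.neighbors import NearestNeighbors
    nn = NearestNeighbors(n_neighbors=k + 1).fit(z)
    dist, _ = nn.kneighbors(z)
    return np.sort(dist[:, -1])


@dataclass
class ScalingStats:
    """Per-variable mean/SD on the log scale, learned on a training set."""

    mean: pd.Series
    sd: pd.Series
    zero_replacement: pd.Series

    @property
    def variables(self) -> list[str]:
        return list(self.mean.index)

    def to_dict(self) -> dict:
        return {
            "variables": self.variables,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "zero_replacement": self.zero_replacement.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScalingStats":
        idx = pd.Index(d["variables"])
        return cls(pd.Series(d["mean"], index=idx),
                   pd.Series(d["sd"], index=idx),
                   pd.Series(d["zero_replacement"], index=idx))


def log_standardize(samples: SampleTable | pd.DataFrame,
                    stats: ScalingStats | None = None
                    ) -> tuple[pd.DataFrame, ScalingStats]:
    """Natural-log transform then autoscale (mean 0, unit variance).

    Zeros are replaced by half the smallest positive value of the variable
    before taking logs.  With ``stats`` given the stored training statistics
    are applied (projection mode); otherwise they are computed here and
    variables constant on the training set are dropped with a warning.
    """
    values = samples.values_matrix() if isinstance(samples, SampleTable) else samples
    if (values.to_numpy(dtype=float) < 0).any():
        raise DataError("negative values cannot be log-transformed")

    if stats is None:
        half_min = {}
        for col in values.columns:
            pos = values[col][values[col] > 0]
            half_min[col] = float(pos.min()) / 2.0 if len(pos) else 1.0
        repl = pd.Series(half_min)
        logx = np.log(values.where(values > 0, repl, axis=1))
        mean = logx.mean(axis=0)
        sd = logx.std(axis=0, ddof=1)
        keep = sd > 0
        if not keep.all():
            logger.warning("dropping constant variables: %s",
                           list(sd.index[~keep]))
        stats = ScalingStats(mean[keep], sd[keep], repl[keep])
        z = (logx.loc[:, keep] - stats.mean) / stats.sd
        return z, stats

    missing = [v for v in stats.variables if v not in values.columns]
    if missing:
        raise DataError(f"projection input missing variables: {missing[:10]}")
    sub = values[stats.variables]
    logx = np.log(sub.where(sub > 0, stats.zero_replacement, axis=1))
    z = (logx - stats.mean) / stats.sd
    return z, stats
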