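"""The samples x variables exchange table used by every pipeline stage.

A :class:`SampleTable` wraps a single :class:`pandas.DataFrame` holding
per-sample metadata (subject, cohort, dates, age, sex, severity, ...) next to
the quantified variables (metabolite concentrations in mmol/L, lipoprotein
parameters in mg/dL, normalized spectral inflammation bins).  Keeping one flat
frame makes CSV round-trips trivial and lets pandas do the heavy lifting.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError

#: Metadata columns always present, in canonical order.
METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "cohort",
    "collection_date",
    "hospitalization_date",
    "covid_report_date",
    "age",
    "sex",
    "severity",
    "vaccinated",
    "true_recovery_day",
]

#: Columns added by day assignment (preprocess stage); optional otherwise.
ASSIGNED_COLUMNS = ["days_since_covid", "acute"]

COHORTS = ("HC", "AC", "RE", "NHR")
DATE_COLUMNS = ["collection_date", "hospitalization_date", "covid_report_date"]


@dataclass
class SampleTable:
    """Samples x quantified variables plus per-sample metadata."""

    data: pd.DataFrame
    variables: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.variables:
            meta = set(METADATA_COLUMNS) | set(ASSIGNED_COLUMNS)
            self.variables = [c for c in self.data.columns if c not in meta]
        self.validate()

    # -- accessors ---------------------------------------------------------
    def values_matrix(self) -> pd.DataFrame:
        """Numeric samples x variables block, indexed by sample_id."""
        return self.data.set_index("sample_id")[self.variables]

    @property
    def meta(self) -> pd.DataFrame:
        cols = [c for c in METADATA_COLUMNS + ASSIGNED_COLUMNS if c in self.data.columns]
        return self.data[cols]

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "SampleTable":
        return SampleTable(self.data.copy(), list(self.variables))

    def subset(self, mask) -> "SampleTable":
        return SampleTable(self.data.loc[mask].reset_index(drop=True), list(self.variables))

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        df = self.data
        missing = [c for c in METADATA_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"SampleTable missing metadata columns: {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise DataError(f"duplicate sample_id values: {dupes[:5]}")
        vals = df[self.variables].to_numpy(dtype=float)
        if vals.size and (~np.isfinite(vals)).any():
            raise DataError("non-finite values in variable columns")
        if vals.size and (vals < 0).any():
            raise DataError("negative concentrations in variable columns")
        hc = df["cohort"] == "HC"
        if hc.any():
            bad = df.loc[hc, ["hospitalization_date", "covid_report_date"]].notna()
            if bad.to_numpy().any():
                raise DataError("HC rows must not carry hospitalization/covid dates")

    # -- serialization -----------------------------------------------------
    def to_csv(self, path, provenance: dict | None = None) -> None:
        """Write as CSV; provenance is emitted as '#'-prefixed header lines."""
        with open(path, "w") as fh:
            for key, val in (provenance or {}).items():
                fh.write(f"# {key}: {val}\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "SampleTable":
        df = pd.read_csv(path, comment="#")
        for col in DATE_COLUMNS:
            if col in df.columns:
                df[col] = pd.to_datetime(df[col], errors="coerce")
        return cls(df)
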