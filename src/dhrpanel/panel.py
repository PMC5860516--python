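"""Practice-month panel container.

A :class:`PracticePanel` holds long-format practice-month records (one row per
practice per month) together with projected planar practice coordinates in
meters.  It is the common currency between the synthetic generator, the
mixed-model stage and the spatiotemporal diagnostics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

REQUIRED_COLUMNS = ("practice_id", "month", "log_rate")
LOCATION_COLUMNS = ("easting", "northing")


@dataclass
class PracticePanel:
    """Long-format panel of practice-month outcome records.

    Parameters
    ----------
    records : pandas.DataFrame
        Columns ``practice_id``, ``month`` (integer index 1..T), ``log_rate``
        and one column per covariate.
    locations : pandas.DataFrame
        Indexed by ``practice_id`` with columns ``easting`` and ``northing``
        (projected planar coordinates, meters).
    covariate_names : tuple of str
        Names of the covariate columns in ``records``.
    """

    records: pd.DataFrame
    locations: pd.DataFrame
    covariate_names: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        for col in REQUIRED_COLUMNS:
            if col not in self.records.columns:
                raise ValueError(f"panel records are missing required column {col!r}")
        for col in self.covariate_names:
            if col not in self.records.columns:
                raise ValueError(f"panel records are missing covariate column {col!r}")
        for col in LOCATION_COLUMNS:
            if col not in self.locations.columns:
                raise ValueError(f"locations are missing required column {col!r}")

        months = self.records["month"].to_numpy()
        if not np.issubdtype(np.asarray(months).dtype, np.integer):
            if not np.allclose(months, np.round(months)):
                raise ValueError("month indices must be integers")
            self.records = self.records.assign(month=np.round(months).astype(int))

        located = set(self.locations.index)
        present = set(self.records["practice_id"])
        orphans = sorted(present - located)
        if orphans:
            raise ValueError(
                f"practices without a location: {', '.join(map(str, orphans))}"
            )

        for pid, grp in self.records.groupby("practice_id"):
            m = grp["month"].to_numpy()
            if np.any(np.diff(m) <= 0):
                raise ValueError(f"months not strictly increasing for practice {pid!r}")

    # -- convenience --------------------------------------------------------
    @property
    def n_practices(self) -> int:
        return self.records["practice_id"].nunique()

    @property
    def n_months(self) -> int:
        return self.records["month"].nunique()

    @property
    def is_complete(self) -> bool:
        """True when every practice has a record for every month."""
        return len(self.records) == self.n_practices * self.n_months

    def area_series(self) -> pd.Series:
        """Area-wide monthly mean of the log rate (ignoring missing records)."""
        return self.records.groupby("month")["log_rate"].mean()

    def wide(self, column: str = "log_rate") -> pd.DataFrame:
        """Pivot to a practices x months matrix (NaN where a record is absent)."""
        return self.records.pivot(index="practice_id", columns="month", values=column)
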