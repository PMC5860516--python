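"""Daily-to-monthly temperature handling, including lagged monthly averaging.

The area-wide seasonal model regresses a monthly outcome on the average daily
mean temperature in each month, optionally lagged so that the value paired with
month *t* is the mean of the daily temperatures recorded ``lag`` days before
each calendar day of month *t*.  A lag of "1 month" means the plain mean of the
previous calendar month.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

#: canonical candidate lags: days, or "1m" for one calendar month
DEFAULT_LAGS = (0, 7, 14, 21, "1m")


def lag_days(lag) -> float:
    """Nominal duration of a lag choice in days (used only for ordering/ties)."""
    if isinstance(lag, str):
        if lag not in ("1m", "1 month", "1month"):
            raise ValueError(f"unknown lag {lag!r}")
        return 30.44
    return float(lag)


def lag_label(lag) -> str:
    return "1m" if isinstance(lag, str) else f"{int(lag)}d"


def month_starts(anchor, n_months: int) -> pd.DatetimeIndex:
    anchor = pd.Timestamp(anchor)
    if anchor.day != 1:
        raise ValueError("calendar anchor must be the first day of a month")
    return pd.date_range(anchor, periods=n_months, freq="MS")


def lag_temperature(daily: pd.Series, lag, anchor=None, n_months: int | None = None) -> pd.Series:
    """Monthly means of a daily temperature series, shifted back by ``lag``.

    Parameters
    ----------
    daily : pandas.Series
        Daily values with a contiguous ``DatetimeIndex``.
    lag : int or "1m"
        Lag in days, or ``"1m"`` for the mean of the previous calendar month.
    anchor : date-like, optional
        First day of month 1.  Defaults to the first first-of-month date in
        the index (generated series usually carry lead-in days, so callers
        normally pass this explicitly).
    n_months : int, optional
        Number of months to produce.  Defaults to the number of complete
        calendar months covered from ``anchor``.

    Returns
    -------
    pandas.Series
        Indexed by month 1..n_months; months whose shifted window is not fully
        covered by the daily series are NaN (and a warning is emitted).
    """
    if not isinstance(daily.index, pd.DatetimeIndex):
        raise TypeError("daily temperature series must have a DatetimeIndex")
    daily = daily.sort_index()

    if anchor is None:
        firsts = daily.index[daily.index.day == 1]
        if len(firsts) == 0:
            raise ValueError("cannot infer anchor: no first-of-month date in index")
        anchor = firsts[0]
    anchor = pd.Timestamp(anchor)
    if anchor.day != 1:
        raise ValueError("anchor must be the first day of a month")

    if n_months is None:
        last = daily.index[-1]
        n_months = (last.year - anchor.year) * 12 + (last.month - anchor.month)
        nxt = (pd.Timestamp(last) + pd.Timedelta(days=1))
        if nxt.day == 1:
            n_months += 1
        if n_months < 1:
            raise ValueError("daily series does not cover a full month from anchor")

    starts = month_starts(anchor, n_months)
    values = np.full(n_months, np.nan)
    lookup = daily.reindex(
        pd.date_range(daily.index[0], daily.index[-1], freq="D")
    )

    one_month = isinstance(lag, str)
    if one_month and lag not in ("1m", "1 month", "1month"):
        raise ValueError(f"unknown lag {lag!r}")

    n_masked = 0
    for t, start in enumerate(starts):
        if one_month:
            w0 = start - pd.offsets.MonthBegin(1)
            days = pd.date_range(w0, start - pd.Timedelta(days=1), freq="D")
        else:
            end = start + pd.offsets.MonthBegin(1) - pd.Timedelta(days=1)
            days = pd.date_range(start, end, freq="D") - pd.Timedelta(days=int(lag))
        window = lookup.reindex(days)
        if window.isna().any():
            n_masked += 1
            continue
        values[t] = window.mean()

    if n_masked:
        warnings.warn(
            f"{n_masked} month(s) lack full daily coverage at lag {lag!r}; "
            "left missing",
            UserWarning,
            stacklevel=2,
        )
    return pd.Series(values, index=pd.RangeIndex(1, n_months + 1, name="month"))
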