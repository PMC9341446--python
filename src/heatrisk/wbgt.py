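"""Approximate wet-bulb globe temperature (WBGT) and heat-alert band summaries.

The WBGT is a composite heat-stress index (°C) combining air temperature,
humidity, solar radiation and wind.  This module implements the regression
approximation used operationally in Japan to estimate the daily maximum WBGT
from readily available meteorology,

    WBGT = 0.735*Tmax + 0.0374*RH + 0.00292*Tmax*RH
           + 7.619*SR - 4.557*SR^2 - 0.0572*WS - 4.064

with Tmax the daily maximum air temperature (°C), RH the relative humidity
(%), SR the global solar radiation (kW/m^2) and WS the average wind speed
(m/s), together with the five-level alert banding of the Japanese heatstroke
warning system (<21, 21-25, 25-28, 28-31, >=31 °C) and summaries of how band
occupancy evolves over multi-year windows.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "BANDS",
    "BAND_COLUMNS",
    "compute_wbgt",
    "classify_band",
    "band_proportions",
    "band_trend",
]

#: The five alert bands, coldest first.  Boundaries are left-closed so that
#: e.g. a WBGT of exactly 28.0 °C falls in the "28-31" band and 31.0 °C in
#: ">=31" ("31 °C or more" is its own level in the warning system).
BANDS: tuple[str, ...] = ("<21", "21-25", "25-28", "28-31", ">=31")

#: Band boundaries in °C (left-closed intervals between consecutive edges).
BAND_EDGES: tuple[float, ...] = (21.0, 25.0, 28.0, 31.0)

#: Column names used for band proportions in tabular output, same order as BANDS.
BAND_COLUMNS: tuple[str, ...] = ("p_lt21", "p_21_25", "p_25_28", "p_28_31", "p_ge31")

# Regression coefficients of the operational WBGT approximation.
_C_TASMAX = 0.735
_C_RH = 0.0374
_C_TASMAX_RH = 0.00292
_C_SR = 7.619
_C_SR2 = -4.557
_C_WS = -0.0572
_C_INTERCEPT = -4.064

#: Solar radiation above this value (kW/m^2) almost certainly means the input
#: is in W/m^2; a warning is emitted rather than silently producing garbage.
SR_UNIT_SUSPECT = 5.0


def _validate_driver(name: str, value: np.ndarray) -> None:
    if not np.all(np.isfinite(value)):
        raise ValueError(f"non-finite value in field '{name}'")


def compute_wbgt(tasmax, rh, sr, ws):
    """Approximate daily maximum WBGT (°C) from daily meteorological drivers.

    Parameters
    ----------
    tasmax : float or array-like
        Daily maximum air temperature, °C.
    rh : float or array-like
        Relative humidity, %.  Must lie in [0, 100].
    sr : float or array-like
        Global solar radiation, kW/m^2 (not W/m^2; values above 5 trigger a
        unit warning).  Must be non-negative.
    ws : float or array-like
        Average wind speed, m/s.  Must be non-negative.

    Returns
    -------
    float or ndarray
        The approximate WBGT, same shape as the broadcast inputs.
    """
    tasmax = np.asarray(tasmax, dtype=float)
    rh = np.asarray(rh, dtype=float)
    sr = np.asarray(sr, dtype=float)
    ws = np.asarray(ws, dtype=float)

    _validate_driver("tasmax", tasmax)
    _validate_driver("rh", rh)
    _validate_driver("sr", sr)
    _validate_driver("ws", ws)
    if np.any((rh < 0.0) | (rh > 100.0)):
        raise ValueError("field 'rh' must lie in [0, 100] (percent)")
    if np.any(sr < 0.0):
        raise ValueError("field 'sr' must be non-negative (kW/m^2)")
    if np.any(ws < 0.0):
        raise ValueError("field 'ws' must be non-negative (m/s)")
    if np.any(sr > SR_UNIT_SUSPECT):
        warnings.warn(
            "solar radiation exceeds 5 kW/m^2; input may be in W/m^2 "
            "(the approximation expects kW/m^2)",
            UserWarning,
            stacklevel=2,
        )

    wbgt = (
        _C_TASMAX * tasmax
        + _C_RH * rh
        + _C_TASMAX_RH * tasmax * rh
        + _C_SR * sr
        + _C_SR2 * sr**2
        + _C_WS * ws
        + _C_INTERCEPT
    )
    return wbgt if wbgt.ndim else float(wbgt)


def classify_band(wbgt):
    """Map WBGT values (°C) to the five alert bands.

    Intervals are left-closed: 28.0 °C is "28-31" and 31.0 °C is ">=31".
    Accepts a scalar (returns a string) or an array (returns an object array).
    """
    arr = np.asarray(wbgt, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("field 'wbgt' must be finite")
    idx = np.searchsorted(BAND_EDGES, arr, side="right")
    labels = np.asarray(BANDS, dtype=object)[idx]
    return labels if arr.ndim else str(labels)


def _prepare_daily(df: pd.DataFrame) -> pd.DataFrame:
    """Normalise a daily WBGT table: datetime dates, no Feb 29, unique days."""
    if "wbgt_c" not in df.columns:
        raise ValueError("expected a 'wbgt_c' column")
    out = df.copy()
    out["date"] = pd.to_datetime(out["date"])
    if out["date"].duplicated().any():
        dup = out.loc[out["date"].duplicated(), "date"].iloc[0]
        raise ValueError(f"duplicate date in series: {dup.date()}")
    # Each year contributes exactly 365 days to every denominator.
    leap = (out["date"].dt.month == 2) & (out["date"].dt.day == 29)
    return out.loc[~leap].sort_values("date").reset_index(drop=True)


def band_proportions(days: pd.DataFrame, window_length_years: int = 5) -> pd.DataFrame:
    """Per-window proportions of days falling in each alert band.

    Parameters
    ----------
    days : DataFrame
        Columns ``date`` and ``wbgt_c``; must cover whole calendar years.
        Feb 29 is dropped, so every year counts 365 days.
    window_length_years : int
        Length of the consecutive, non-overlapping windows, anchored at the
        first year of the series.  Must divide the span exactly.

    Returns
    -------
    DataFrame
        One row per window with ``window_start``, the five band-proportion
        columns (summing to 1) and ``n_days``.
    """
    if window_length_years < 1:
        raise ValueError("window_length_years must be >= 1")
    daily = _prepare_daily(days)
    if daily.empty:
        raise ValueError("empty WBGT series")

    years = daily["date"].dt.year
    counts_per_year = years.value_counts()
    short = counts_per_year[counts_per_year != 365]
    if not short.empty:
        raise ValueError(
            "series must cover whole calendar years; "
            f"year(s) with != 365 non-leap days: {sorted(short.index.tolist())}"
        )
    year_list = np.sort(counts_per_year.index.to_numpy())
    if not np.array_equal(year_list, np.arange(year_list[0], year_list[-1] + 1)):
        raise ValueError("series years must be consecutive")
    n_years = len(year_list)
    if n_years % window_length_years != 0:
        raise ValueError(
            f"{n_years} year(s) do not divide into whole {window_length_years}-year "
            "windows (partial trailing window rejected)"
        )

    daily["band"] = classify_band(daily["wbgt_c"].to_numpy())
    window_start = year_list[0] + window_length_years * (
        (years.to_numpy() - year_list[0]) // window_length_years
    )
    daily["window_start"] = window_start

    rows = []
    for start, grp in daily.groupby("window_start", sort=True):
        n = len(grp)
        row: dict[str, object] = {"window_start": int(start)}
        counts = grp["band"].value_counts()
        for band, col in zip(BANDS, BAND_COLUMNS):
            row[col] = counts.get(band, 0) / n
        row["n_days"] = n
        rows.append(row)
    return pd.DataFrame(rows)


def band_trend(summaries: pd.DataFrame, threshold_band: str = "ge28") -> float:
    """OLS slope of a high-WBGT band proportion across windows.

    Parameters
    ----------
    summaries : DataFrame
        Output of :func:`band_proportions` (>= 2 windows).
    threshold_band : {"ge28", "ge31"}
        ``"ge28"`` sums the top two bands (days at or above 28 °C);
        ``"ge31"`` uses the top band only.

    Returns
    -------
    float
        Slope in percentage points per window (per 5-year step for the
        default windows).
    """
    if len(summaries) < 2:
        raise ValueError("need at least 2 windows to estimate a trend")
    if threshold_band == "ge28":
        y = summaries["p_28_31"].to_numpy() + summaries["p_ge31"].to_numpy()
    elif threshold_band == "ge31":
        y = summaries["p_ge31"].to_numpy()
    else:
        raise ValueError("threshold_band must be 'ge28' or 'ge31'")
    x = np.arange(len(summaries), dtype=float)
    slope = np.polyfit(x, 100.0 * y, 1)[0]
    return float(slope)
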