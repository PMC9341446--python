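"""Project fitted dose-response models onto future climate and demography.

A fitted model gives the expected transports per million per day as a
function of WBGT.  Risk is assumed to occur only in the May 1 - Sep 30
season (153 days).  For each future year the seasonal per-million risk is
summed over days and multiplied by that year's projected age-group
population (in millions) to give an expected annual transport count; annual
counts are then aggregated over consecutive multi-year windows (mean per
year by default, sum optionally).  Bootstrap parameter draws are pushed
through the same map to obtain percentile intervals, and counts are
expressed as fold-changes against a baseline window.

Note the deliberate age-group mismatch inherited from the data sources: the
dose-response models are fitted on 0-17 / 18-64 / 65+ case data but applied
to population projections tabulated as 0-14 / 15-64 / 65+.
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .dose_response import FitResult, ModelParams, predict_risk

__all__ = [
    "SEASON_DAYS",
    "AGE_GROUP_TO_PROJECTION",
    "seasonal_annual_risk",
    "interpolate_population",
    "project_counts",
    "projection_ci",
    "fold_change",
]

#: May (31) + June (30) + July (31) + August (31) + September (30).
SEASON_DAYS = 153

#: Mapping from fitting age groups to population-projection age groups.
AGE_GROUP_TO_PROJECTION = {"0-17": "0-14", "18-64": "15-64", "65+": "65+"}

_SEASON = (5, 1, 9, 30)


def _season_dates(year: int) -> pd.DatetimeIndex:
    return pd.date_range(f"{year}-05-01", f"{year}-09-30", freq="D")


def _seasonal_frame(wbgt_series: pd.DataFrame) -> pd.DataFrame:
    df = wbgt_series.copy()
    df["date"] = pd.to_datetime(df["date"])
    md = df["date"].dt.month * 100 + df["date"].dt.day
    return df[(md >= 501) & (md <= 930)]


def seasonal_annual_risk(params: ModelParams, wbgt_year: pd.DataFrame) -> float:
    """Expected seasonal transports per million for one year.

    ``wbgt_year`` must contain ``date`` and ``wbgt_c`` covering every day of
    May 1 - Sep 30 of a single year; the 153 daily risks are summed.
    """
    df = _seasonal_frame(wbgt_year)
    if df.empty:
        raise ValueError("no May-September days in series")
    years = df["date"].dt.year.unique()
    if len(years) != 1:
        raise ValueError(f"expected a single year, got {sorted(years.tolist())}")
    expected = _season_dates(int(years[0]))
    missing = expected.difference(pd.DatetimeIndex(df["date"]))
    if len(missing):
        gaps = ", ".join(d.strftime("%Y-%m-%d") for d in missing[:10])
        more = "" if len(missing) <= 10 else f" (+{len(missing) - 10} more)"
        raise ValueError(f"missing seasonal days: {gaps}{more}")
    return float(np.sum(predict_risk(params, df["wbgt_c"].to_numpy())))


def interpolate_population(pop: pd.DataFrame, years: Sequence[int]) -> pd.Series:
    """Population per year for one group, linearly interpolated between
    tabulated projection years.  ``pop`` has columns ``year``, ``population``."""
    tab = pop.sort_values("year")
    xs = tab["year"].to_numpy(dtype=float)
    ys = tab["population"].to_numpy(dtype=float)
    years = np.asarray(list(years), dtype=float)
    if years.min() < xs.min() or years.max() > xs.max():
        missing = [int(y) for y in years if y < xs.min() or y > xs.max()]
        raise ValueError(f"population projection does not cover years {missing}")
    return pd.Series(np.interp(years, xs, ys), index=np.asarray(years, dtype=int))


def _annual_counts(
    params: ModelParams, seasonal: pd.DataFrame, pop_by_year: pd.Series
) -> pd.Series:
    """Expected annual counts = seasonal risk sum x population(year)/1e6."""
    T = seasonal["wbgt_c"].to_numpy(dtype=float)
    year = seasonal["date"].dt.year.to_numpy()
    risk = predict_risk(params, T)
    sums = pd.Series(risk).groupby(year).sum()
    return sums * pop_by_year.loc[sums.index].to_numpy() / 1e6


def _check_complete_seasons(seasonal: pd.DataFrame) -> np.ndarray:
    counts = seasonal.groupby(seasonal["date"].dt.year).size()
    bad = counts[counts != SEASON_DAYS]
    if not bad.empty:
        raise ValueError(
            "incomplete May-September coverage in years "
            f"{sorted(bad.index.tolist())}"
        )
    years = np.sort(counts.index.to_numpy())
    if not np.array_equal(years, np.arange(years[0], years[-1] + 1)):
        raise ValueError("projection years must be consecutive")
    return years


def _windows(years: np.ndarray, window: int) -> np.ndarray:
    if len(years) % window != 0:
        raise ValueError(
            f"{len(years)} year(s) do not divide into whole {window}-year windows"
        )
    return years[0] + window * ((years - years[0]) // window)


def project_counts(
    fit: FitResult | ModelParams,
    wbgt_series: pd.DataFrame,
    population: pd.DataFrame,
    window: int = 5,
    window_stat: str = "mean",
) -> pd.DataFrame:
    """Point projection of transport counts per window.

    Parameters
    ----------
    fit : FitResult or ModelParams
        Fitted dose-response model.
    wbgt_series : DataFrame
        ``date``, ``wbgt_c`` covering complete May-September seasons of
        consecutive years; the year span must divide into whole windows.
    population : DataFrame
        ``year``, ``population`` for the (projection) age group; missing
        years are linearly interpolated.
    window : int
        Window length in years.
    window_stat : {"mean", "sum"}
        Report the mean annual count per window (default; keeps the y-scale
        of annual transports) or the window total.

    Returns
    -------
    DataFrame with ``window_start`` and ``expected_count``.
    """
    params = fit.params if isinstance(fit, FitResult) else fit
    if window_stat not in ("mean", "sum"):
        raise ValueError("window_stat must be 'mean' or 'sum'")
    seasonal = _seasonal_frame(wbgt_series)
    years = _check_complete_seasons(seasonal)
    pop_by_year = interpolate_population(population, years)
    annual = _annual_counts(params, seasonal, pop_by_year)
    win = _windows(annual.index.to_numpy(), window)
    agg = annual.groupby(win).mean() if window_stat == "mean" else annual.groupby(win).sum()
    return pd.DataFrame(
        {"window_start": agg.index.astype(int), "expected_count": agg.to_numpy()}
    )


def projection_ci(
    fit: FitResult,
    draws: Sequence[ModelParams],
    wbgt_series: pd.DataFrame,
    population: pd.DataFrame,
    window: int = 5,
    window_stat: str = "mean",
    percentiles: tuple[float, float] = (2.5, 97.5),
) -> pd.DataFrame:
    """Point projection with bootstrap percentile intervals per window.

    Every parameter draw is pushed through :func:`project_counts`' map and
    the empirical percentiles (default 2.5/97.5) are taken per window.
    Deterministic given the draw set.
    """
    if len(draws) == 0:
        raise ValueError("need at least one bootstrap draw")
    point = project_counts(fit, wbgt_series, population, window, window_stat)

    seasonal = _seasonal_frame(wbgt_series)
    years = _check_complete_seasons(seasonal)
    pop_by_year = interpolate_population(population, years)
    win_of_year = _windows(years, window)
    # precompute per-year slices once; each draw is then one vectorised pass
    seasonal = seasonal.sort_values("date")
    T = seasonal["wbgt_c"].to_numpy(dtype=float)
    year_idx = np.searchsorted(years, seasonal["date"].dt.year.to_numpy())
    n_windows = len(point)
    win_idx_of_year = np.searchsorted(np.unique(win_of_year), win_of_year)

    out = np.empty((len(draws), n_windows))
    scale = pop_by_year.to_numpy() / 1e6
    per_window_years = np.bincount(win_idx_of_year)
    for b, params in enumerate(draws):
        risk = predict_risk(params, T)
        annual = np.bincount(year_idx, weights=risk, minlength=len(years)) * scale
        totals = np.bincount(win_idx_of_year, weights=annual, minlength=n_windows)
        out[b] = totals / per_window_years if window_stat == "mean" else totals
    lo, hi = np.percentile(out, percentiles, axis=0)
    point["ci_low"] = lo
    point["ci_high"] = hi
    return point


def fold_change(results: pd.DataFrame, baseline_window: int) -> pd.DataFrame:
    """Expected counts as ratios to a baseline window's expected count."""
    base = results.loc[results["window_start"] == baseline_window, "expected_count"]
    if base.empty:
        raise ValueError(f"baseline window {baseline_window} not present")
    base_val = float(base.iloc[0])
    if base_val <= 0:
        raise ValueError("baseline expected count must be positive")
    out = results.copy()
    out["fold_vs_baseline"] = out["expected_count"] / base_val
    return out
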