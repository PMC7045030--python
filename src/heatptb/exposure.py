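"""Exposure preparation: apparent temperature, station backfill, lag means,
log transforms and warm-season restriction.

The daily analysis table ("daily series") produced here is a pandas DataFrame
indexed by a gap-free ``DatetimeIndex`` (within each seasonal block) with the
columns

======================  =======================================================
column                  meaning
======================  =======================================================
temp_c, dewpoint_c      air / dew-point temperature, deg C
at_c                    apparent temperature, deg C
at2_c                   mean apparent temperature over lag days 0-1, deg C
wind_ms                 mean wind speed, m/s
solar_wm2               mean solar radiation, W/m^2
precip_mm               total precipitation, mm
ln_precip               ln(precip_mm + offset), offset defaults to 1.0 mm
o3_ppb                  8-h max ozone, ppb
pm10_ugm3, ln_pm10      daily mean PM10 and its natural log
no2_ppb, ln_no2         daily mean NO2 and its natural log
======================  =======================================================
"""

from __future__ import annotations

from collections.abc import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "compute_apparent_temperature",
    "backfill_station",
    "lag_mean",
    "log_transform_skewed",
    "restrict_warm_season",
    "exposure_percentiles",
    "build_daily_series",
]

#: Months retained by the warm-season restriction (May through September).
WARM_SEASON_MONTHS = (5, 6, 7, 8, 9)

#: Default offset (mm) added before log-transforming precipitation, which has
#: a large point mass at exactly zero.
PRECIP_LOG_OFFSET = 1.0


def compute_apparent_temperature(temp_c, dewpoint_c):
    """Apparent temperature (deg C) from air and dew-point temperature.

    ``AT = -2.653 + 0.994 * T + 0.0153 * Td**2``

    The dew-point term uses the signed value squared, so negative dew points
    are legal inputs. Non-finite inputs propagate to NaN output.

    Parameters
    ----------
    temp_c, dewpoint_c : scalar or array-like
        Air temperature and dew-point temperature in deg C.

    Returns
    -------
    Same shape as the inputs; NaN wherever either input is missing.
    """
    t = np.asarray(temp_c, dtype=float)
    td = np.asarray(dewpoint_c, dtype=float)
    at = -2.653 + 0.994 * t + 0.0153 * td**2
    if at.ndim == 0:
        return float(at)
    if isinstance(temp_c, pd.Series):
        return pd.Series(at, index=temp_c.index, name="at_c")
    return at


def backfill_station(primary: pd.Series, secondary: pd.Series):
    """Fill gaps in a primary-station series from a secondary station.

    Primary values are kept wherever present; days missing at the primary
    station are taken from the secondary; days missing at both stations stay
    missing (this is legal and left for downstream models to drop).

    Returns
    -------
    filled : pandas.Series
        Aligned to the union of both date indexes.
    source : pandas.Series of str
        Per-day provenance: ``"primary"``, ``"secondary"`` or ``"missing"``.
    """
    idx = primary.index.union(secondary.index)
    p = primary.reindex(idx)
    s = secondary.reindex(idx)
    filled = p.where(p.notna(), s)
    source = pd.Series("missing", index=idx, dtype=object)
    source[s.notna()] = "secondary"
    source[p.notna()] = "primary"
    return filled, source


def lag_mean(series: pd.Series, lags: Iterable[int] = (0, 1)) -> pd.Series:
    """Mean of a daily series over a set of non-negative day lags.

    Day ``d`` maps to ``mean(series[d - L] for L in lags)``. Days without the
    full lag history (the first ``max(lags)`` days) are missing. Requires a
    sorted, duplicate-free date index; raises ``ValueError`` otherwise.
    """
    if not series.index.is_monotonic_increasing:
        raise ValueError("lag_mean requires a sorted date index")
    if series.index.has_duplicates:
        raise ValueError("lag_mean requires a duplicate-free date index")
    lags = sorted(set(int(x) for x in lags))
    if any(lag < 0 for lag in lags):
        raise ValueError("lags must be non-negative")
    if isinstance(series.index, pd.DatetimeIndex):
        # Date-aware: a day right after a calendar gap has no lag history and
        # comes out missing, instead of silently borrowing the pre-gap value.
        full = pd.date_range(series.index.min(), series.index.max(), freq="D")
        s = series.reindex(full)
        acc = sum(s.shift(lag) for lag in lags) / len(lags)
        return acc.loc[series.index]
    acc = sum(series.shift(lag) for lag in lags)
    return acc / len(lags)


def log_transform_skewed(series, offset: float = 0.0, floor: float = 1e-6):
    """Natural log of a non-negative skewed variable, ``ln(x + offset)``.

    ``offset`` defaults to 0 (with a small positive ``floor`` guard for exact
    zeros); use ``offset=1.0`` for precipitation, where over half the days are
    exactly zero. Raises ``ValueError`` if any ``x + offset`` is negative.
    """
    x = np.asarray(series, dtype=float) + offset
    if np.any(x[np.isfinite(x)] < 0):
        raise ValueError("log transform undefined: x + offset < 0")
    if offset == 0.0:
        x = np.where(x < floor, floor, x)
    out = np.log(x)
    if isinstance(series, pd.Series):
        return pd.Series(out, index=series.index)
    return out


def restrict_warm_season(table: pd.DataFrame, months=WARM_SEASON_MONTHS) -> pd.DataFrame:
    """Retain rows whose month falls in the warm season (default May-Sep)."""
    if len(table) == 0:
        return table
    return table.loc[table.index.month.isin(list(months))]


def exposure_percentiles(series: pd.Series, q=(50, 95), min_n: int = 20) -> dict:
    """Empirical exposure percentiles (linear-interpolation convention).

    Returns a dict like ``{"p50": ..., "p95": ...}`` computed from the
    non-missing values. Raises ``ValueError`` with fewer than ``min_n``
    observations, since the tail percentile would be unstable.
    """
    x = np.asarray(series, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < min_n:
        raise ValueError(f"need >= {min_n} non-missing values, got {x.size}")
    vals = np.percentile(x, q, method="linear")
    return {f"p{int(qq)}": float(v) for qq, v in zip(q, vals)}


def build_daily_series(
    weather: pd.DataFrame,
    pollutants: pd.DataFrame | None = None,
    precip_offset: float = PRECIP_LOG_OFFSET,
) -> pd.DataFrame:
    """Assemble the daily analysis table from raw meteorology and pollutants.

    Computes apparent temperature, its lag 0-1 mean (computed on the full
    calendar before any season restriction, so 1 May uses 30 April), and the
    log transforms of precipitation, PM10 and NO2.
    """
    out = weather.copy()
    out["at_c"] = compute_apparent_temperature(out["temp_c"], out["dewpoint_c"])
    out["at2_c"] = lag_mean(out["at_c"], (0, 1))
    out["ln_precip"] = log_transform_skewed(out["precip_mm"], offset=precip_offset)
    if pollutants is not None:
        for col in ("o3_ppb", "pm10_ugm3", "no2_ppb"):
            if col in pollutants.columns:
                out[col] = pollutants[col].reindex(out.index)
        if "pm10_ugm3" in out.columns:
            out["ln_pm10"] = log_transform_skewed(out["pm10_ugm3"])
        if "no2_ppb" in out.columns:
            out["ln_no2"] = log_transform_skewed(out["no2_ppb"])
    return out
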