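"""Descriptive summary tables: demographics of the case series and daily
exposure distributions among case days."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["summarize_demographics", "summarize_exposures", "DEMOGRAPHIC_BLOCKS"]

#: Categorical blocks summarized, in display order: column -> {level: label}.
DEMOGRAPHIC_BLOCKS = {
    "race": None,
    "smoking": None,
    "prenatal_care": None,
    "age_group": None,
    "education": None,
    "month": None,
}

#: Exposure columns: (column, label, geometric-mean flag, log offset)
EXPOSURE_VARS = (
    ("at2_c", "Two-day mean apparent temperature, degC", False, 0.0),
    ("at2_excess_c", "Two-day mean apparent temperature above threshold, degC", False, 0.0),
    ("solar_wm2", "Mean solar radiation (W/m2)", False, 0.0),
    ("precip_mm", "Total precipitation (mm)", True, 1.0),
    ("wind_ms", "Mean wind speed (m/s)", False, 0.0),
    ("o3_ppb", "Maximum 8 hour average ozone (ppb)", False, 0.0),
    ("pm10_ugm3", "Mean particulate matter, 10 um or less (ug/m3)", True, 0.0),
    ("no2_ppb", "Mean nitrogen dioxide (ppb)", True, 0.0),
)


def summarize_demographics(records: pd.DataFrame, columns=None) -> pd.DataFrame:
    """Counts and percentages per level of each categorical column.

    Percentages are ``100 * n / total`` rounded to one decimal; missing
    values are reported as their own ``"Missing"`` level. Raises
    ``ValueError`` on empty input.
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty record table")
    total = len(records)
    columns = columns or [c for c in records.columns if c != "date"]
    rows = [{"variable": "Total", "level": "", "n": total, "percent": 100.0}]
    for col in columns:
        vals = records[col].astype(object).where(records[col].notna(), "Missing")
        counts = vals.value_counts(dropna=False)
        levels = [lv for lv in counts.index if lv != "Missing"]
        if "Missing" in counts.index:
            levels.append("Missing")
        for lv in levels:
            n = int(counts[lv])
            rows.append(
                {
                    "variable": col,
                    "level": lv,
                    "n": n,
                    "percent": round(100.0 * n / total, 1),
                }
            )
    return pd.DataFrame(rows)


def _geometric_mean(x: np.ndarray, offset: float) -> float:
    shifted = x + offset
    shifted = np.where(shifted <= 0, 1e-6, shifted)
    return float(np.exp(np.mean(np.log(shifted))) - offset)


def summarize_exposures(series: pd.DataFrame, at_threshold_c: float | None = None) -> pd.DataFrame:
    """N / median / mean / min / max per exposure variable.

    Skewed variables (precipitation, PM10, NO2) report geometric means; the
    apparent-temperature excess above ``at_threshold_c`` (default: the
    median) is included as its own variable.
    """
    if len(series) == 0:
        raise ValueError("cannot summarize an empty series")
    work = series.copy()
    if "at2_c" in work.columns:
        thr = float(work["at2_c"].median()) if at_threshold_c is None else at_threshold_c
        work["at2_excess_c"] = np.maximum(0.0, work["at2_c"] - thr)
    rows = []
    for col, label, geo, offset in EXPOSURE_VARS:
        if col not in work.columns:
            continue
        x = work[col].dropna().to_numpy(dtype=float)
        if x.size == 0:
            continue
        mean = _geometric_mean(x, offset) if geo else float(np.mean(x))
        rows.append(
            {
                "variable": label,
                "n": int(x.size),
                "median": float(np.median(x)),
                "mean": mean,
                "min": float(np.min(x)),
                "max": float(np.max(x)),
            }
        )
    return pd.DataFrame(rows)
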