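"""Heat-index computation and exposure preparation.

Implements the US National Weather Service heat-index algorithm (Steadman
simple formula below the 80 degF threshold, Rothfusz regression with the
low- and high-humidity adjustments above it), unweighted grid-to-ZIP
aggregation, warm-season climate-subtype percentile tables, and trailing
moving averages.

Heat index is computed in degF internally (the NWS equations' native scale)
and reported in degC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

WARM_SEASON_MONTHS = (5, 6, 7, 8, 9)


def _c_to_f(c):
    return np.asarray(c, dtype=float) * 9.0 / 5.0 + 32.0


def _f_to_c(f):
    return (np.asarray(f, dtype=float) - 32.0) * 5.0 / 9.0


def compute_heat_index(tmax_c, rhmin_pct):
    """NWS heat index (degC) from daily max temperature (degC) and min RH (%).

    The Steadman simple formula ``0.5*(T + 61 + (T-68)*1.2 + RH*0.094)``
    (T in degF) is used when its average with T falls below 80 degF;
    otherwise the Rothfusz nine-coefficient regression applies, with the
    NWS low-humidity adjustment (RH < 13%, 80 <= T <= 112 degF) and
    high-humidity adjustment (RH > 85%, 80 <= T <= 87 degF).

    Accepts scalars or arrays; vectorized. Raises ``ValueError`` for
    non-finite inputs or relative humidity outside [0, 100].
    """
    t = np.asarray(tmax_c, dtype=float)
    r = np.asarray(rhmin_pct, dtype=float)
    scalar = t.ndim == 0 and r.ndim == 0
    t, r = np.broadcast_arrays(np.atleast_1d(t), np.atleast_1d(r))
    if not (np.all(np.isfinite(t)) and np.all(np.isfinite(r))):
        raise ValueError("heat index inputs must be finite")
    if np.any((r < 0) | (r > 100)):
        raise ValueError("relative humidity must lie in [0, 100] percent")

    tf = _c_to_f(t)
    simple = 0.5 * (tf + 61.0 + (tf - 68.0) * 1.2 + r * 0.094)

    hi = (
        -42.379
        + 2.04901523 * tf
        + 10.14333127 * r
        - 0.22475541 * tf * r
        - 6.83783e-3 * tf**2
        - 5.481717e-2 * r**2
        + 1.22874e-3 * tf**2 * r
        + 8.5282e-4 * tf * r**2
        - 1.99e-6 * tf**2 * r**2
    )
    low = (r < 13) & (tf >= 80.0) & (tf <= 112.0)
    with np.errstate(invalid="ignore"):
        adj_low = ((13.0 - r) / 4.0) * np.sqrt(
            np.clip((17.0 - np.abs(tf - 95.0)) / 17.0, 0.0, None)
        )
    hi = np.where(low, hi - adj_low, hi)
    high = (r > 85) & (tf >= 80.0) & (tf <= 87.0)
    adj_high = ((r - 85.0) / 10.0) * ((87.0 - tf) / 2.0)
    hi = np.where(high, hi + adj_high, hi)

    out_f = np.where((simple + tf) / 2.0 < 80.0, simple, hi)
    out = _f_to_c(out_f)
    return float(out[0]) if scalar else out


def aggregate_grid_to_zip(grid_values: pd.DataFrame, mapping: pd.DataFrame,
                          value_col: str = "value") -> pd.DataFrame:
    """Unweighted mean of grid-cell values per ZIP.

    ``grid_values`` holds (cell_id, <value_col>) and ``mapping`` holds
    (cell_id, zip).  ZIPs with no mapped cell are absent from the output.
    """
    if mapping.empty:
        warnings.warn("empty cell-to-ZIP mapping: no ZIP values produced")
        return pd.DataFrame(columns=["zip", value_col])
    if grid_values["cell_id"].duplicated().any():
        raise ValueError("duplicate cell_id in grid values")
    merged = mapping.merge(grid_values, on="cell_id", how="inner")
    out = merged.groupby("zip", as_index=False)[value_col].mean()
    return out


@dataclass
class HeatPercentileTable:
    """Pooled warm-season heat-index sample for one climate subtype.

    Percentiles use the right-continuous ECDF, 100 * (#values <= x) / n;
    the inverse is nearest-rank, so quantile(0) is the sample minimum and
    quantile(100) the maximum.
    """

    subtype: str
    values: np.ndarray = field(repr=False)  # sorted, ascending

    def __post_init__(self):
        v = np.sort(np.asarray(self.values, dtype=float))
        if v.size == 0:
            raise ValueError(f"empty heat-index sample for subtype {self.subtype}")
        object.__setattr__(self, "values", v)

    def percentile(self, x) -> np.ndarray | float:
        """Map heat index (degC) to its subtype percentile in [0, 100]."""
        x = np.asarray(x, dtype=float)
        p = 100.0 * np.searchsorted(self.values, x, side="right") / self.values.size
        return float(p) if p.ndim == 0 else p

    def quantile(self, p) -> np.ndarray | float:
        """Nearest-rank inverse: heat index (degC) at percentile p."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p > 100)):
            raise ValueError("percentile must lie in [0, 100]")
        n = self.values.size
        k = np.maximum(np.ceil(p / 100.0 * n).astype(int), 1)
        q = self.values[k - 1]
        return float(q) if p.ndim == 0 else q


def compute_percentiles(records: pd.DataFrame, climate: pd.DataFrame,
                        season: tuple[int, ...] = WARM_SEASON_MONTHS,
                        ) -> dict[str, HeatPercentileTable]:
    """Build per-subtype percentile tables from pooled warm-season ZIP-days.

    Pools every warm-season ZIP-day heat-index value (case and control days
    alike) across all years and all ZIPs of a subtype, so one degC value maps
    to different percentiles in different climates. Subtypes with no
    warm-season data are dropped with a warning.
    """
    rec = records.merge(climate[["zip", "subtype"]], on="zip", how="left")
    months = pd.to_datetime(rec["date"]).dt.month
    rec = rec[months.isin(season)]
    tables: dict[str, HeatPercentileTable] = {}
    for subtype, grp in rec.groupby("subtype"):
        vals = grp["heat_index"].dropna().to_numpy()
        if vals.size == 0:
            warnings.warn(f"subtype {subtype} has no warm-season heat data; excluded")
            continue
        tables[subtype] = HeatPercentileTable(subtype=str(subtype), values=vals)
    return tables


def to_percentile(heat_index, subtype: str,
                  tables: dict[str, HeatPercentileTable]):
    """Percentile of a heat-index value within its climate subtype."""
    if subtype not in tables:
        raise KeyError(f"unknown climate subtype {subtype!r}")
    return tables[subtype].percentile(heat_index)


def moving_average(series: pd.DataFrame, window: int = 3,
                   value_cols: tuple[str, ...] = ("heat_index", "pm25"),
                   ) -> pd.DataFrame:
    """Trailing moving average per ZIP: day t averages days t, t-1, ..., t-w+1.

    Calendar-aware: a day whose preceding calendar days are absent from the
    panel gets a missing value (rather than silently averaging non-adjacent
    rows). Pre-season lags (e.g. late April feeding the first May days) are
    used whenever present in the input.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out = series.copy()
    out["date"] = pd.to_datetime(out["date"])
    out = out.sort_values(["zip", "date"]).reset_index(drop=True)
    for col in value_cols:
        acc = out[col].astype(float).copy()
        for lag in range(1, window):
            shifted = out[["zip", "date", col]].copy()
            shifted["date"] = shifted["date"] + pd.Timedelta(days=lag)
            lagged = out[["zip", "date"]].merge(
                shifted, on=["zip", "date"], how="left")[col]
            acc = acc + lagged.to_numpy()
        out[col] = acc / window
    return out


def percentile_tables_to_frame(tables: dict[str, HeatPercentileTable]) -> pd.DataFrame:
    """Long-format (subtype, heat_index) audit dump of the pooled samples."""
    parts = [pd.DataFrame({"subtype": t.subtype, "heat_index": t.values})
             for t in tables.values()]
    return pd.concat(parts, ignore_index=True) if parts else pd.DataFrame(
        columns=["subtype", "heat_index"])


def percentile_tables_from_frame(frame: pd.DataFrame) -> dict[str, HeatPercentileTable]:
    return {str(s): HeatPercentileTable(subtype=str(s),
                                        values=g["heat_index"].to_numpy())
            for s, g in frame.groupby("subtype")}
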