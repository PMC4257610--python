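"""Readers and writers for abundance and weather CSV files.

Abundance files carry one row per day: an ISO-8601 ``date`` column plus one
integer-count column per species.  Weather files are daily station exports;
a :class:`WeatherDialect` absorbs header and unit variants (NCDC exports,
for example, report precipitation in tenths of mm).

Missing days inside the observed span are flagged as NaN gaps, never
silently filled; downstream analyses decide how to resolve them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .timeseries import TimeSeries, WeatherSeries

logger = logging.getLogger("mosqspec")

__all__ = [
    "AbundanceDialect",
    "WeatherDialect",
    "read_abundance",
    "read_weather",
    "write_abundance",
    "write_weather",
]


@dataclass
class AbundanceDialect:
    """Column mapping for abundance CSVs (default: ``date`` + species columns)."""

    date_column: str = "date"
    species_map: dict[str, str] = field(default_factory=dict)  # canonical -> file header


@dataclass
class WeatherDialect:
    """Column names and unit codes for a daily weather export.

    ``temperature_unit``: ``"C"`` or ``"tenths_C"``;
    ``precipitation_unit``: ``"mm"`` or ``"tenths_mm"``.
    """

    date_column: str = "date"
    temperature_column: str = "temperature"
    precipitation_column: str = "precipitation"
    humidity_column: str = "relative_humidity"
    dew_point_column: Optional[str] = "dew_point"
    wind_speed_column: Optional[str] = "wind_speed"
    temperature_unit: str = "C"
    precipitation_unit: str = "mm"


def _load_dated_frame(path: str | Path, date_column: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if date_column not in df.columns:
        raise ValueError(f"missing mandatory column {date_column!r} in {path}")
    df[date_column] = pd.to_datetime(df[date_column])
    if df[date_column].duplicated().any():
        dups = df.loc[df[date_column].duplicated(), date_column].dt.date.unique()
        raise ValueError(f"duplicated dates in {path}: {list(dups)[:5]}")
    return df.sort_values(date_column).reset_index(drop=True)


def _reindex_daily(df: pd.DataFrame, date_column: str) -> pd.DataFrame:
    """Reindex onto the contiguous daily span; absent days become NaN rows."""
    full = pd.date_range(df[date_column].iloc[0], df[date_column].iloc[-1], freq="D")
    out = df.set_index(date_column).reindex(full)
    n_missing = len(full) - len(df)
    if n_missing:
        missing = full.difference(pd.DatetimeIndex(df[date_column]))
        logger.warning(
            "gap report: %d missing day(s) between %s and %s (first: %s)",
            n_missing, full[0].date(), full[-1].date(), missing[0].date(),
        )
    return out


def read_abundance(
    path: str | Path,
    species: str,
    dialect: AbundanceDialect | None = None,
) -> TimeSeries:
    """Read the daily count series of one species from an abundance CSV.

    Unknown species names raise with the list of available columns; missing
    days inside the span surface as NaN gaps in the returned series.
    """
    dialect = dialect or AbundanceDialect()
    df = _load_dated_frame(path, dialect.date_column)
    column = dialect.species_map.get(species, species)
    if column not in df.columns:
        available = [c for c in df.columns if c != dialect.date_column]
        raise ValueError(
            f"species {species!r} not found in {path}; available: {available}"
        )
    daily = _reindex_daily(df[[dialect.date_column, column]], dialect.date_column)
    values = daily[column].to_numpy(dtype=float)
    finite = values[~np.isnan(values)]
    if np.any(finite < 0):
        raise ValueError(f"negative counts in column {column!r}")
    return TimeSeries(daily.index, values, delta_t=1.0, label=species)


def read_weather(
    path: str | Path,
    dialect: WeatherDialect | None = None,
    max_gap: int = 7,
) -> WeatherSeries:
    """Read a daily weather export, normalising units to deg C and mm/day.

    Missing weather days are linearly interpolated up to ``max_gap`` days
    (gaps are logged through the package logger); longer gaps raise.
    """
    dialect = dialect or WeatherDialect()
    df = _load_dated_frame(path, dialect.date_column)
    for required in (dialect.temperature_column, dialect.precipitation_column):
        if required not in df.columns:
            raise ValueError(f"missing mandatory column {required!r} in {path}")
    daily = _reindex_daily(df, dialect.date_column)

    def _column(name: Optional[str], scale: float = 1.0) -> Optional[np.ndarray]:
        if name is None or name not in daily.columns:
            return None
        vals = daily[name].to_numpy(dtype=float) * scale
        s = pd.Series(vals)
        spans = s.isna()
        if spans.any():
            run = spans.groupby((~spans).cumsum()).sum().max()
            if run > max_gap:
                raise ValueError(
                    f"weather column {name!r} has a gap of {int(run)} days "
                    f"(> max_gap={max_gap})"
                )
            vals = s.interpolate(limit_direction="both").to_numpy()
            logger.info("read_weather: interpolated %d missing value(s) in %s",
                        int(spans.sum()), name)
        return vals

    t_scale = 0.1 if dialect.temperature_unit == "tenths_C" else 1.0
    p_scale = 0.1 if dialect.precipitation_unit == "tenths_mm" else 1.0
    temperature = _column(dialect.temperature_column, t_scale)
    precipitation = _column(dialect.precipitation_column, p_scale)
    humidity = _column(dialect.humidity_column)
    if humidity is None:
        humidity = np.full(len(daily), np.nan)
    return WeatherSeries(
        dates=daily.index,
        temperature=temperature,
        precipitation=np.clip(precipitation, 0.0, None),
        relative_humidity=np.clip(humidity, 0.0, 100.0),
        dew_point=_column(dialect.dew_point_column),
        wind_speed=_column(dialect.wind_speed_column),
    )


def write_abundance(path: str | Path, series: list[TimeSeries]) -> None:
    """Write one or more aligned daily count series to the abundance layout."""
    base = series[0]
    frame = pd.DataFrame({"date": base.dates.strftime("%Y-%m-%d")})
    for ts in series:
        if len(ts) != len(base) or not (ts.dates == base.dates).all():
            raise ValueError("all series must share one calendar")
        col = ts.values
        frame[ts.label or "count"] = np.where(
            np.isnan(col), "", np.round(col).astype("int64", copy=False).astype(str)
        ) if np.isnan(col).any() else np.round(col).astype("int64")
    frame.to_csv(path, index=False)


def write_weather(path: str | Path, weather: WeatherSeries) -> None:
    frame = pd.DataFrame(
        {
            "date": weather.dates.strftime("%Y-%m-%d"),
            "temperature": weather.temperature,
            "precipitation": weather.precipitation,
            "relative_humidity": weather.relative_humidity,
        }
    )
    if weather.dew_point is not None:
        frame["dew_point"] = weather.dew_point
    if weather.wind_speed is not None:
        frame["wind_speed"] = weather.wind_speed
    frame.to_csv(path, index=False)
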