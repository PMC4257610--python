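"""Daily time-series containers shared by every analysis in the package.

The common currency is :class:`TimeSeries`: a uniformly sampled series of
values on a calendar of days, with an explicit sampling interval ``delta_t``
(1 day for raw trap counts, 7 days for weekly subsamples).  Gaps are
represented as NaN and must be resolved (interpolated or segmented) before
spectral or correlation analysis.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

logger = logging.getLogger("mosqspec")

__all__ = ["TimeSeries", "WeatherSeries", "fill_gaps", "moving_average"]


@dataclass
class TimeSeries:
    """A uniformly sampled series of daily (or subsampled) values.

    Parameters
    ----------
    dates : pandas.DatetimeIndex
        Strictly increasing calendar days, equally spaced by ``delta_t``.
    values : numpy.ndarray
        Measurements; NaN marks a missing day (a gap).
    delta_t : float
        Sampling interval in days (1 for raw data, 7 for weekly subsamples).
    label : str
        Species or variable name, free text.
    """

    dates: pd.DatetimeIndex
    values: np.ndarray
    delta_t: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.dates) != len(self.values):
            raise ValueError(
                f"dates ({len(self.dates)}) and values ({len(self.values)}) "
                "differ in length"
            )
        if len(self.dates) < 2:
            raise ValueError("a TimeSeries needs at least 2 samples")
        diffs = np.diff(self.dates.view("int64"))
        step = self.delta_t * 86_400_000_000_000  # days -> ns
        if np.any(diffs <= 0):
            raise ValueError("dates must be strictly increasing with no duplicates")
        if not np.allclose(diffs, step):
            raise ValueError(
                f"dates are not equally spaced by delta_t={self.delta_t} days"
            )

    def __len__(self) -> int:
        return len(self.values)

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def has_gaps(self) -> bool:
        return bool(np.isnan(self.values).any())

    def gap_spans(self) -> list[tuple[int, int]]:
        """Return (start, stop) index pairs of NaN runs, stop exclusive."""
        isnan = np.isnan(self.values)
        spans: list[tuple[int, int]] = []
        i = 0
        while i < len(isnan):
            if isnan[i]:
                j = i
                while j < len(isnan) and isnan[j]:
                    j += 1
                spans.append((i, j))
                i = j
            else:
                i += 1
        return spans

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"date": self.dates, self.label or "value": self.values})

    def with_values(self, values: np.ndarray, label: Optional[str] = None) -> "TimeSeries":
        return replace(
            self, values=np.asarray(values, dtype=float),
            label=self.label if label is None else label,
        )


@dataclass
class WeatherSeries:
    """Aligned daily weather forcing on one contiguous calendar.

    Temperature in deg C, precipitation in mm/day (non-negative), relative
    humidity in percent.  Dew point (deg C) and wind speed (m/s) are
    optional.  Trailing 10-day moving averages — the smoothing the
    development, survival and blood-meal responses are driven by — are
    exposed as properties.
    """

    dates: pd.DatetimeIndex
    temperature: np.ndarray
    precipitation: np.ndarray
    relative_humidity: np.ndarray
    dew_point: Optional[np.ndarray] = None
    wind_speed: Optional[np.ndarray] = None
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        n = len(self.dates)
        for name in ("temperature", "precipitation", "relative_humidity"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if len(arr) != n:
                raise ValueError(f"{name} length {len(arr)} != calendar length {n}")
            setattr(self, name, arr)
        for name in ("dew_point", "wind_speed"):
            arr = getattr(self, name)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if len(arr) != n:
                    raise ValueError(f"{name} length {len(arr)} != calendar length {n}")
                setattr(self, name, arr)
        diffs = np.diff(self.dates.view("int64"))
        if len(diffs) and not np.all(diffs == 86_400_000_000_000):
            raise ValueError("WeatherSeries requires a contiguous daily calendar")
        with np.errstate(invalid="ignore"):
            if np.any(self.precipitation < 0):
                raise ValueError("precipitation must be >= 0")
            rh = self.relative_humidity
            if np.any((rh < 0) | (rh > 100)):
                raise ValueError("relative_humidity must lie in [0, 100]")

    def __len__(self) -> int:
        return len(self.dates)

    def _trailing(self, name: str, window: int = 10) -> np.ndarray:
        key = (name, window)
        if key not in self._cache:
            s = pd.Series(getattr(self, name))
            self._cache[key] = s.rolling(window, min_periods=1).mean().to_numpy()
        return self._cache[key]

    @property
    def temperature_10d(self) -> np.ndarray:
        """Trailing 10-day mean temperature (deg C)."""
        return self._trailing("temperature")

    @property
    def precipitation_10d(self) -> np.ndarray:
        """Trailing 10-day mean precipitation (mm/day)."""
        return self._trailing("precipitation")

    @property
    def humidity_10d(self) -> np.ndarray:
        """Trailing 10-day mean relative humidity (%)."""
        return self._trailing("relative_humidity")

    def series(self, name: str) -> TimeSeries:
        """Expose one weather variable as a TimeSeries."""
        return TimeSeries(self.dates, getattr(self, name), delta_t=1.0, label=name)


def fill_gaps(ts: TimeSeries, max_gap: int) -> TimeSeries:
    """Linearly interpolate NaN gaps of length <= ``max_gap`` days.

    Longer gaps raise, reporting the offending span; observed values are
    never altered.  Gaps touching either end of the series cannot be
    bracketed and also raise.
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if not ts.has_gaps:
        return ts
    spans = ts.gap_spans()
    for start, stop in spans:
        length = stop - start
        if length > max_gap:
            raise ValueError(
                f"gap of {length} days at {ts.dates[start].date()}.."
                f"{ts.dates[stop - 1].date()} exceeds max_gap={max_gap}"
            )
        if start == 0 or stop == len(ts):
            raise ValueError(
                f"gap at series boundary (index {start}..{stop}) cannot be "
                "interpolated; trim the series instead"
            )
    filled = pd.Series(ts.values).interpolate(method="linear", limit_area="inside")
    logger.info(
        "fill_gaps: interpolated %d gap(s) totalling %d day(s) in %r",
        len(spans), sum(b - a for a, b in spans), ts.label,
    )
    return ts.with_values(filled.to_numpy())


def moving_average(ts: TimeSeries, window: int) -> TimeSeries:
    """Trailing (causal) moving average over ``window`` days.

    The mean is taken over the ``window`` samples ending at each day; the
    first ``window - 1`` days use the partial available window, so output
    length equals input length and ``window=1`` is the identity.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    out = pd.Series(ts.values).rolling(window, min_periods=1).mean().to_numpy()
    return ts.with_values(out)
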