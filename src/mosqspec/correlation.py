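"""ACF/PACF estimation and the weekly-subsampling degradation experiment.

The autocorrelation at lag k measures the average correlation between
abundance values k sampling steps apart; the partial autocorrelation
removes the indirect correlation routed through the intermediate lags.
Estimation is delegated to statsmodels: the biased (1/n) ACF normalisation
(which keeps the sample autocovariance sequence positive semidefinite) and
the Durbin–Levinson recursion on that ACF for the PACF.

Subsampling a daily series to one collection day per week raises the
Nyquist period from 2 days to 2 weeks: any structure faster than 14 days
present in the daily correlogram is unrecoverable from every weekly
subsample, and the apparent memory of the series can shrink dramatically
depending on which weekday happens to be sampled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.tsa.stattools import acf as sm_acf
from statsmodels.tsa.stattools import pacf as sm_pacf

from .timeseries import TimeSeries

__all__ = [
    "CorrelationFunction",
    "acf",
    "pacf",
    "weekly_subsample",
    "significant_positive_run",
]


@dataclass
class CorrelationFunction:
    """ACF or PACF values on a lag grid with a white-noise 95% band.

    ``ci`` is the symmetric band half-width 1.96/sqrt(n) under the
    large-sample white-noise approximation; ``lags`` are in sampling steps,
    ``delta_t`` converts them to days.
    """

    lags: np.ndarray
    values: np.ndarray
    ci: float
    kind: str  # "ACF" | "PACF"
    n: int
    delta_t: float = 1.0

    @property
    def lag_days(self) -> np.ndarray:
        return self.lags * self.delta_t

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"lag_days": self.lag_days, "value": self.values, "ci": self.ci}
        )


def _check(ts: TimeSeries, max_lag: int) -> np.ndarray:
    if ts.has_gaps:
        raise ValueError("series has gaps; fill or segment before correlating")
    if max_lag >= len(ts) / 2:
        raise ValueError(
            f"max_lag={max_lag} too large for series of length {len(ts)} "
            "(must be < length/2)"
        )
    if max_lag < 1:
        raise ValueError("max_lag must be >= 1")
    return np.asarray(ts.values, dtype=float)


def acf(ts: TimeSeries, max_lag: int) -> CorrelationFunction:
    """Sample autocorrelation function with the biased (1/n) normalisation."""
    x = _check(ts, max_lag)
    values = sm_acf(x, nlags=max_lag, adjusted=False, fft=True)
    return CorrelationFunction(
        lags=np.arange(max_lag + 1),
        values=values,
        ci=1.96 / np.sqrt(len(x)),
        kind="ACF",
        n=len(x),
        delta_t=ts.delta_t,
    )


def pacf(ts: TimeSeries, max_lag: int) -> CorrelationFunction:
    """Partial autocorrelations via Durbin–Levinson on the biased sample ACF."""
    x = _check(ts, max_lag)
    values = sm_pacf(x, nlags=max_lag, method="ldb")
    return CorrelationFunction(
        lags=np.arange(max_lag + 1),
        values=values,
        ci=1.96 / np.sqrt(len(x)),
        kind="PACF",
        n=len(x),
        delta_t=ts.delta_t,
    )


def weekly_subsample(ts: TimeSeries) -> list[TimeSeries]:
    """Split a daily series into the 7 weekly series of each collection day.

    Subsample j keeps days j, j+7, j+14, ... (offsets 0..6 from the series
    start); each output has ``delta_t = 7`` and is labelled with its weekday
    name from the input calendar.  Together the 7 outputs partition the
    input values (up to the trailing partial week).
    """
    if ts.delta_t != 1.0:
        raise ValueError("weekly_subsample requires a daily (delta_t=1) series")
    if len(ts) < 14:
        raise ValueError("need at least 14 days to form weekly subsamples")
    out = []
    for offset in range(7):
        dates = ts.dates[offset::7]
        values = ts.values[offset::7]
        weekday = dates[0].day_name()
        out.append(TimeSeries(dates, values, delta_t=7.0,
                              label=f"{ts.label}[{weekday}]"))
    return out


def significant_positive_run(cf: CorrelationFunction) -> float:
    """Longest initial run of lags whose correlation exceeds the +95% band.

    Returns the run length in DAYS (lag index times delta_t); 0 if the
    lag-1 value is already inside the band.  This operationalises
    "significantly positive out to about L weeks" statements.
    """
    run = 0
    for lag, value in zip(cf.lags, cf.values):
        if lag == 0:
            continue
        if value > cf.ci:
            run = lag
        else:
            break
    return float(run * cf.delta_t)
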