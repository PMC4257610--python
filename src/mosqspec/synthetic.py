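"""Synthetic weather and abundance generators.

These emulate the statistical structure the analyses assume — an annual
temperature sinusoid with AR(1) noise and intermittent rainfall; abundance
with superposed periodicities, strong overdispersed day-to-day fluctuation
and zero winters — so every downstream module is testable without any
external data.  They make no attempt to match a particular station's
climate, only the structural features the methods respond to.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .timeseries import TimeSeries, WeatherSeries

__all__ = [
    "WeatherGenParams",
    "AbundanceGenParams",
    "generate_weather",
    "generate_abundance",
    "generate_density_series",
]

_EPOCH = "2004-01-01"


@dataclass
class WeatherGenParams:
    """Parameters of the synthetic daily weather model.

    Temperature is an annual sinusoid (period 365.25 d) of mean
    ``mean_temp`` and amplitude ``annual_amplitude`` plus AR(1) noise with
    innovation sd ``temp_noise_sd`` and coefficient ``temp_noise_ar1``.
    Rainfall is wet/dry Bernoulli(``rain_prob``) with exponential wet-day
    depth of mean ``rain_mean`` mm — enough structure to exercise the
    1 mm/day dryness threshold and the rainfall-activity response, with no
    storm clustering.  Relative humidity sits at ``rh_base`` %, boosted by
    ``rh_rain_boost`` on wet days.
    """

    mean_temp: float = 17.0
    annual_amplitude: float = 10.0
    temp_noise_sd: float = 2.0
    temp_noise_ar1: float = 0.7
    rain_prob: float = 0.3
    rain_mean: float = 8.0
    rh_base: float = 65.0
    rh_rain_boost: float = 20.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.rain_prob <= 1.0:
            raise ValueError(f"rain_prob must be in [0, 1], got {self.rain_prob}")
        if self.rain_mean <= 0:
            raise ValueError(f"rain_mean must be > 0, got {self.rain_mean}")
        if not 0.0 <= self.temp_noise_ar1 < 1.0:
            raise ValueError(
                f"temp_noise_ar1 must be in [0, 1), got {self.temp_noise_ar1}"
            )
        if self.temp_noise_sd < 0 or self.annual_amplitude < 0:
            raise ValueError("temp_noise_sd and annual_amplitude must be >= 0")


@dataclass
class AbundanceGenParams:
    """Parameters of the synthetic abundance model.

    The daily expectation is ``baseline + sum_k amplitudes[k] *
    sin(2 pi t / periods[k])``, floored at zero and zeroed inside
    ``winter_window`` (a day-of-year span, wrap-around allowed).  Counts are
    negative-binomial around that expectation with dispersion ``dispersion``
    (variance = mu + mu^2/dispersion): daily trap catches swing over orders
    of magnitude, far beyond Poisson noise.
    """

    periods: list[float] = field(default_factory=lambda: [365.25, 70.0, 30.0])
    amplitudes: list[float] = field(default_factory=lambda: [60.0, 25.0, 15.0])
    baseline: float = 70.0
    dispersion: float = 1.5
    winter_window: tuple[int, int] | None = (335, 59)  # Dec 1 .. Feb 28
    seed: int = 0

    def validate(self) -> None:
        if len(self.periods) != len(self.amplitudes):
            raise ValueError("periods and amplitudes must have equal length")
        if any(p < 2 for p in self.periods):
            raise ValueError(
                "all periods must be >= 2 days (resolvable at daily sampling)"
            )
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be >= 0")
        if self.baseline < 0 or self.dispersion <= 0:
            raise ValueError("baseline must be >= 0 and dispersion > 0")


def generate_weather(
    n_days: int, params: WeatherGenParams | None = None, start: str = _EPOCH
) -> WeatherSeries:
    """Generate ``n_days`` of synthetic daily weather (reproducible by seed)."""
    params = params or WeatherGenParams()
    params.validate()
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(params.seed)
    t = np.arange(n_days)
    # AR(1) noise at its stationary distribution.
    phi, sd = params.temp_noise_ar1, params.temp_noise_sd
    noise = np.zeros(n_days)
    if sd > 0:
        noise[0] = rng.normal(0.0, sd / np.sqrt(1.0 - phi**2))
        eps = rng.normal(0.0, sd, size=n_days)
        for i in range(1, n_days):
            noise[i] = phi * noise[i - 1] + eps[i]
    temperature = (
        params.mean_temp
        - params.annual_amplitude * np.cos(2 * np.pi * t / 365.25)
        + noise
    )
    wet = rng.random(n_days) < params.rain_prob
    precipitation = np.where(wet, rng.exponential(params.rain_mean, size=n_days), 0.0)
    rh = params.rh_base + np.where(wet, params.rh_rain_boost, 0.0)
    rh = rh + rng.normal(0.0, 3.0, size=n_days)
    return WeatherSeries(
        dates=pd.date_range(start, periods=n_days, freq="D"),
        temperature=temperature,
        precipitation=precipitation,
        relative_humidity=np.clip(rh, 0.0, 100.0),
    )


def _in_window(doy: np.ndarray, window: tuple[int, int]) -> np.ndarray:
    lo, hi = window
    if lo <= hi:
        return (doy >= lo) & (doy <= hi)
    return (doy >= lo) | (doy <= hi)  # wrap around new year


def generate_abundance(
    n_days: int, params: AbundanceGenParams | None = None, start: str = _EPOCH
) -> TimeSeries:
    """Generate an overdispersed daily count series with injected periodicities."""
    params = params or AbundanceGenParams()
    params.validate()
    if n_days < 2:
        raise ValueError("n_days must be >= 2")
    rng = np.random.default_rng(params.seed)
    dates = pd.date_range(start, periods=n_days, freq="D")
    t = np.arange(n_days, dtype=float)
    mu = np.full(n_days, float(params.baseline))
    for period, amp in zip(params.periods, params.amplitudes):
        mu += amp * np.sin(2 * np.pi * t / period)
    mu = np.clip(mu, 0.0, None)
    if params.winter_window is not None:
        mu[_in_window(dates.dayofyear.to_numpy(), params.winter_window)] = 0.0
    # Negative binomial via its Gamma-Poisson mixture: mean mu, size r.
    r = params.dispersion
    lam = np.where(mu > 0, rng.gamma(r, np.maximum(mu, 1e-12) / r), 0.0)
    counts = rng.poisson(lam).astype(float)
    return TimeSeries(dates, counts, delta_t=1.0, label="synthetic")


def generate_density_series(
    model: str,
    r_m: float,
    K: float,
    n: int,
    noise_sd: float = 0.0,
    N0: float | None = None,
    lag: int = 0,
    seed: int = 0,
    start: str = _EPOCH,
) -> TimeSeries:
    """Iterate a Ricker or Gompertz-logistic recursion with log-normal noise.

    Ricker:    N_{t+1} = N_t * exp(r_m * (1 - N_{t-lag} / K) + eps_t)
    Gompertz:  N_{t+1} = N_t * exp(r_m * (1 - log N_{t-lag} / log K) + eps_t)

    with eps_t ~ Normal(0, noise_sd); ``noise_sd = 0`` makes the recursion
    exact.  ``lag`` delays the density term (0 = current abundance).
    """
    model = model.lower()
    if model not in ("ricker", "gompertz"):
        raise ValueError(f"model must be 'ricker' or 'gompertz', got {model!r}")
    if K <= 0:
        raise ValueError("K must be > 0")
    if N0 is None:
        N0 = 0.1 * K
    if N0 <= 0:
        raise ValueError("N0 must be > 0")
    if lag < 0:
        raise ValueError("lag must be >= 0")
    rng = np.random.default_rng(seed)
    N = np.empty(n, dtype=float)
    N[: lag + 1] = N0
    eps = rng.normal(0.0, noise_sd, size=n) if noise_sd > 0 else np.zeros(n)
    logK = np.log(K)
    for t in range(lag, n - 1):
        dens = N[t - lag]
        if model == "ricker":
            growth = r_m * (1.0 - dens / K)
        else:
            growth = r_m * (1.0 - np.log(dens) / logK)
        N[t + 1] = N[t] * np.exp(growth + eps[t])
    dates = pd.date_range(start, periods=n, freq="D")
    return TimeSeries(dates, N, delta_t=1.0, label=f"{model}(r={r_m},K={K})")
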