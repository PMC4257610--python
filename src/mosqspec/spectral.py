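"""Discrete Fourier power spectra on the period grid T_i = N*dt / i.

The power at each period is the squared amplitude of the corresponding
sinusoidal component: the DFT magnitude is scaled by (2/N)^2 so that a
unit-amplitude sinusoid sitting exactly on a grid frequency yields unit
peak power.  No tapering is applied by default; a Hann window is available
as an option and flagged in the output.

The shortest resolvable period at sampling interval dt is the Nyquist
period 2*dt — daily sampling resolves down to 2 days, weekly sampling only
down to 2 weeks; everything faster aliases into apparent noise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

logger = logging.getLogger("mosqspec")

__all__ = [
    "PowerSpectrum",
    "SpectralPeak",
    "nyquist_period",
    "power_spectrum",
    "find_peaks",
]


@dataclass
class PowerSpectrum:
    """Amplitude-squared spectrum on the decreasing period grid N*dt/i, i=1..N/2."""

    periods: np.ndarray  # days, strictly decreasing from N*dt to 2*dt
    power: np.ndarray    # squared oscillation amplitude, >= 0
    n: int               # source sample size
    delta_t: float       # source sampling interval, days
    detrend: str = "mean"
    window: str = "none"
    log_transformed: bool = False

    def variance_from_spectrum(self) -> float:
        """Series variance implied by the spectrum (Parseval).

        Each interior component of amplitude A contributes A^2/2 to the
        variance; the Nyquist component (present for even N) contributes
        A^2/4 under this amplitude normalisation.
        """
        contrib = self.power / 2.0
        if self.n % 2 == 0:
            contrib[-1] = self.power[-1] / 4.0
        return float(np.sum(contrib))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"period_days": self.periods, "power": self.power})


@dataclass
class SpectralPeak:
    """One local maximum of a (possibly smoothed) power spectrum."""

    period: float
    power: float
    rank: int
    band: Optional[tuple[float, float]] = None


def nyquist_period(delta_t: float) -> float:
    """Shortest resolvable period, 2*delta_t, at sampling interval delta_t."""
    if delta_t <= 0:
        raise ValueError(f"delta_t must be > 0, got {delta_t}")
    return 2.0 * delta_t


def power_spectrum(
    ts: TimeSeries,
    detrend: str = "mean",
    window: str = "none",
    log_transform: bool = False,
) -> PowerSpectrum:
    """Compute the amplitude-squared power spectrum of a gapless series.

    ``detrend="mean"`` removes the series mean (the i=0 component) before
    the transform; ``log_transform`` applies log(1+x) first and flags the
    output.  Deterministic.
    """
    if ts.has_gaps:
        raise ValueError(
            "series has gaps; fill_gaps() it or analyse gapless segments"
        )
    if len(ts) < 4:
        raise ValueError("need at least 4 samples for a spectrum")
    if detrend not in ("none", "mean"):
        raise ValueError(f"detrend must be 'none' or 'mean', got {detrend!r}")
    if window not in ("none", "hann"):
        raise ValueError(f"window must be 'none' or 'hann', got {window!r}")
    x = np.asarray(ts.values, dtype=float)
    if log_transform:
        x = np.log1p(x)
    if detrend == "mean":
        x = x - x.mean()
    if window == "hann":
        x = x * np.hanning(len(x))
        logger.info("power_spectrum: Hann taper applied")
    n = len(x)
    X = np.fft.rfft(x)
    i = np.arange(1, n // 2 + 1)
    power = (2.0 / n * np.abs(X[i])) ** 2
    periods = n * ts.delta_t / i
    return PowerSpectrum(
        periods=periods,
        power=power,
        n=n,
        delta_t=ts.delta_t,
        detrend=detrend,
        window=window,
        log_transformed=log_transform,
    )


def _smooth(power: np.ndarray, bins: int) -> np.ndarray:
    if bins <= 1:
        return power
    if bins % 2 == 0:
        raise ValueError("smooth width must be odd")
    kernel = np.ones(bins) / bins
    # reflect-pad so edge bins keep a full window
    half = bins // 2
    padded = np.concatenate([power[half:0:-1], power, power[-2:-2 - half:-1]])
    return np.convolve(padded, kernel, mode="valid")


def find_peaks(
    spec: PowerSpectrum,
    k: int = 1,
    band: Optional[tuple[float, float]] = None,
    smooth: int = 3,
) -> list[SpectralPeak]:
    """Top-``k`` local maxima of the (smoothed) spectrum within a period band.

    The spectrum is smoothed with a ``smooth``-bin moving average (raw
    periodograms of noisy series are jagged; width 1 disables smoothing),
    then strict local maxima are ranked by smoothed power, ties broken
    toward the longer period.  The zero-frequency (mean) component is not
    on the grid and so never reported.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    smoothed = _smooth(spec.power, smooth)
    if smooth > 1:
        logger.info("find_peaks: %d-bin smoothing applied", smooth)
    periods = spec.periods
    if band is not None:
        lo, hi = band
        in_band = (periods >= lo) & (periods <= hi)
        if not in_band.any():
            raise ValueError(
                f"band {band} contains no spectral bins "
                f"(grid spans [{periods[-1]:.3g}, {periods[0]:.3g}] days)"
            )
    else:
        in_band = np.ones_like(periods, dtype=bool)
    # Detect on the smoothed spectrum (plateaus from the smoothing kernel
    # are admitted at their edges), then refine each candidate to the
    # largest raw-power bin among its immediate neighbours.
    p = smoothed
    n_bins = len(p)
    refined: dict[int, float] = {}
    for j in range(n_bins):
        if not in_band[j]:
            continue
        left = p[j - 1] if j > 0 else -np.inf
        right = p[j + 1] if j < n_bins - 1 else -np.inf
        if p[j] >= left and p[j] >= right and (p[j] > left or p[j] > right):
            lo_j, hi_j = max(0, j - 1), min(n_bins, j + 2)
            local = range(lo_j, hi_j)
            best = max(local, key=lambda i: (spec.power[i], -i))
            if in_band[best]:
                refined[best] = float(spec.power[best])
    # rank by raw power desc, ties toward the longer period (smaller index)
    ranked = sorted(refined.items(), key=lambda item: (-item[1], item[0]))
    peaks = [
        SpectralPeak(period=float(periods[j]), power=pw, rank=r + 1,
                     band=tuple(band) if band else None)
        for r, (j, pw) in enumerate(ranked[:k])
    ]
    return peaks
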