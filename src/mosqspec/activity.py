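"""Rainfall-dependent activity-fraction estimation.

Trap counts reflect the host-seeking (active) fraction of the adult
population, not the population itself.  The activity ratio of day t is
estimated as the count divided by the maximum count in a 31-day moving
window — the window maximum standing in for the population that could be
caught under the most favourable conditions.  Binning these ratios by
daily rainfall intensity and taking per-bin medians yields an empirical
activity curve: rising with light rain, collapsing under heavy rain.  A
parametric hump with that shape feeds the simulator's observation layer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .timeseries import TimeSeries

__all__ = [
    "ActivityCurve",
    "activity_ratio_series",
    "bin_by_rainfall",
    "parametric_activity",
    "DEFAULT_BIN_EDGES",
]

# The rainfall intervals are a configurable analysis choice; these defaults
# resolve the drizzle range finely and lump heavy storms.
DEFAULT_BIN_EDGES = (0.0, 0.5, 1.0, 2.0, 5.0, 10.0, 20.0, np.inf)


@dataclass
class ActivityCurve:
    """Per-rainfall-bin medians of the activity ratio."""

    bin_edges: np.ndarray      # increasing, last may be inf
    median_ratio: np.ndarray   # NaN where a bin holds no days
    counts: np.ndarray         # days per bin

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_low": self.bin_edges[:-1],
                "bin_high": self.bin_edges[1:],
                "median_ratio": self.median_ratio,
                "n_days": self.counts,
            }
        )


def activity_ratio_series(
    abundance: TimeSeries, window: int = 31, centered: bool = True
) -> TimeSeries:
    """Ratio of each day's count to the maximum in its moving window.

    The window is centred by default (31 days: 15 either side); a trailing
    window is available.  Windows whose maximum is 0 give an undefined
    (NaN) ratio — all-zero winter stretches carry no activity information
    and would otherwise contaminate the curve.  Defined ratios lie in
    [0, 1] and are invariant to rescaling the abundance.
    """
    if abundance.delta_t != 1.0:
        raise ValueError("activity_ratio_series requires a daily series")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    s = pd.Series(abundance.values)
    if centered:
        win_max = s.rolling(window, min_periods=1, center=True).max()
    else:
        win_max = s.rolling(window, min_periods=1).max()
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(win_max.to_numpy() > 0,
                         abundance.values / win_max.to_numpy(), np.nan)
    return abundance.with_values(ratio, label=f"{abundance.label}.activity_ratio")


def bin_by_rainfall(
    ratios: TimeSeries,
    precipitation: TimeSeries,
    bin_edges=DEFAULT_BIN_EDGES,
) -> ActivityCurve:
    """Median activity ratio per rainfall-intensity interval.

    Days with undefined ratios are excluded; bins holding no days are
    flagged with NaN medians.
    """
    if len(ratios) != len(precipitation) or not (
        ratios.dates == precipitation.dates
    ).all():
        raise ValueError("ratio and precipitation series must share one calendar")
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be increasing with at least 2 edges")
    defined = ~np.isnan(ratios.values)
    r = ratios.values[defined]
    p = precipitation.values[defined]
    idx = np.digitize(p, edges[1:-1], right=False)
    n_bins = len(edges) - 1
    medians = np.full(n_bins, np.nan)
    counts = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        sel = idx == b
        counts[b] = int(sel.sum())
        if counts[b]:
            medians[b] = float(np.median(r[sel]))
    return ActivityCurve(bin_edges=edges, median_ratio=medians, counts=counts)


def parametric_activity(
    precip: float,
    rise: float = 0.4,
    optimum: float = 2.0,
    fall: float = 0.5,
    floor: float = 0.15,
) -> float:
    """Unimodal activity fraction of daily rainfall, in [floor, 1].

    A piecewise log-linear hump: activity climbs from its dry-day level to
    1 at the ``optimum`` rainfall (mm/day), then decays steeply —
    ``exp(-fall * (p - optimum))`` — for heavier rain, never dropping below
    ``floor``.  ``rise`` sets how far below 1 the dry-day level sits:
    activity(0) = exp(-rise * optimum) clipped at the floor.
    """
    if precip < 0:
        raise ValueError("precip must be >= 0")
    if optimum <= 0 or rise < 0 or fall < 0:
        raise ValueError("optimum must be > 0; rise and fall must be >= 0")
    if not 0.0 <= floor <= 1.0:
        raise ValueError("floor must lie in [0, 1]")
    if precip <= optimum:
        value = np.exp(-rise * (optimum - precip))
    else:
        value = np.exp(-fall * (precip - optimum))
    return float(np.clip(value, floor, 1.0))
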