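"""Matplotlib hooks for the standard figures.

Every figure is regenerable from the CSV exports; nothing numeric exists
only inside an image.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .activity import ActivityCurve  # noqa: E402
from .correlation import CorrelationFunction  # noqa: E402
from .spectral import PowerSpectrum  # noqa: E402


def plot_spectrum(spec: PowerSpectrum, path: str, title: str = "") -> None:
    """Period-vs-power figure on a log period axis."""
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.loglog(spec.periods, spec.power, lw=0.8)
    ax.set_xlabel("period (days)")
    ax.set_ylabel("power (amplitude$^2$)")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_correlogram(cf: CorrelationFunction, path: str, title: str = "") -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.stem(cf.lag_days, cf.values, basefmt=" ", markerfmt=".")
    ax.axhline(cf.ci, ls="--", color="tab:blue", lw=0.8)
    ax.axhline(-cf.ci, ls="--", color="tab:blue", lw=0.8)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("lag (days)")
    ax.set_ylabel(cf.kind)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_activity_curve(curve: ActivityCurve, path: str, title: str = "") -> None:
    frame = curve.to_frame().dropna(subset=["median_ratio"])
    centers = [
        lo + (hi - lo) / 2 if hi != float("inf") else lo * 1.5
        for lo, hi in zip(frame["bin_low"], frame["bin_high"])
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(centers, frame["median_ratio"], "o-")
    ax.set_xlabel("daily rainfall (mm/day)")
    ax.set_ylabel("median activity ratio")
    ax.set_ylim(0, 1.05)
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
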