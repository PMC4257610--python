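"""Species parameter files and the biological response functions they define.

Each species is one YAML file holding every stage-specific parameter:
development-time power laws d = A * T^(-a) (T the trailing 10-day mean
temperature, deg C), gonotrophic-cycle distribution, daily survival curves,
dryness penalty, density-dependence slopes, blood-meal success probability,
egg-batch distribution, and overwintering behaviour.  Two species ship with
the package:

* ``ae_vexans`` — a floodwater mosquito: overwinters as eggs, embryonated
  eggs hatch only when inundated by sufficient rainfall, gonotrophic cycle
  a truncated normal on [7, 13] days with mean 10, blood-meal success
  increasing linearly with relative humidity.
* ``cs_melanura`` — a slow-developing swamp breeder: overwinters as larvae,
  gonotrophic mean decreases with temperature, blood-meal success an
  increasing quadratic in temperature, larval survival 1 under zero
  crowding and wet conditions.

Numeric coefficients not fixed by published stage-duration anchors are
documented stand-ins (see docs/methods.md) and live only in the YAML files,
never in code.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from scipy.stats import norm, truncnorm

__all__ = ["SpeciesParams", "load_species", "available_species"]

_MAX_DAYS = 400  # cap on any sampled residence time, days


def _quadratic(t: float, opt: float, peak: float, half_width: float) -> float:
    """Downward parabola peaking at (opt, peak), zero at opt +/- half_width."""
    return peak * (1.0 - ((t - opt) / half_width) ** 2)


@dataclass
class SpeciesParams:
    """All stage-specific biological parameters for one species."""

    name: str
    # development: stage -> {"A": float, "a": float}
    development: dict
    stage_time_sd: float
    temp_floor: float
    # gonotrophic: {"mean": {...}, "sd": float, "bounds": [lo, hi] | None}
    gonotrophic: dict
    # survival: {"egg": float, "larva": {...}, "adult": {...},
    #            "dry_penalty": float, "dry_threshold_mm": float}
    survival: dict
    # density_dependence: {"egg_slope": float, "larva_slope": float}
    density_dependence: dict
    bloodmeal: dict
    eggs_per_batch: dict
    female_fraction: float
    overwinter_stage: str  # "egg" | "larva"
    diapause_temp: float
    hatch_rain_threshold_mm: Optional[float]
    _pmf_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        for stage, coeff in self.development.items():
            if coeff["A"] <= 0 or coeff["a"] <= 0:
                raise ValueError(
                    f"{self.name}: development power law for {stage} needs "
                    f"A > 0 and a > 0, got {coeff}"
                )
        bounds = self.gonotrophic.get("bounds")
        if bounds is not None:
            lo, hi = bounds
            mean_cfg = self.gonotrophic["mean"]
            if mean_cfg.get("type") == "constant" and not lo <= mean_cfg["value"] <= hi:
                raise ValueError(
                    f"{self.name}: gonotrophic bounds {bounds} must bracket "
                    f"the mean {mean_cfg['value']}"
                )
        if self.overwinter_stage not in ("egg", "larva"):
            raise ValueError("overwinter_stage must be 'egg' or 'larva'")
        if not 0.0 < self.female_fraction <= 1.0:
            raise ValueError("female_fraction must be in (0, 1]")

    # -- development -------------------------------------------------------

    def dev_mean(self, stage: str, t10: float) -> float:
        """Mean residence time (days) in ``stage`` at 10-day mean temperature t10.

        The power law diverges at 0 deg C, so t10 is clamped at the
        configured floor; below the diapause threshold the caller freezes
        development clocks instead.
        """
        coeff = self.development[stage]
        t = max(t10, self.temp_floor)
        return coeff["A"] * t ** (-coeff["a"])

    def development_pmf(self, stage: str, t10: float) -> np.ndarray:
        """PMF over whole-day residence times: round(Normal(mean, sd)), floor 1."""
        key = (stage, round(float(t10), 1))
        if key not in self._pmf_cache:
            mean = self.dev_mean(stage, key[1])
            self._pmf_cache[key] = _rounded_normal_pmf(mean, self.stage_time_sd)
        return self._pmf_cache[key]

    # -- gonotrophic cycle -------------------------------------------------

    def gono_mean(self, t10: float) -> float:
        cfg = self.gonotrophic["mean"]
        if cfg["type"] == "constant":
            return float(cfg["value"])
        if cfg["type"] == "linear_temp":
            return max(cfg.get("min", 1.0), cfg["intercept"] + cfg["slope"] * t10)
        raise ValueError(f"unknown gonotrophic mean type {cfg['type']!r}")

    def gono_pmf(self, t10: float) -> np.ndarray:
        key = ("gono", round(float(t10), 1))
        if key not in self._pmf_cache:
            mean = self.gono_mean(key[1])
            sd = self.gonotrophic["sd"]
            bounds = self.gonotrophic.get("bounds")
            if bounds is not None:
                self._pmf_cache[key] = _rounded_truncnorm_pmf(mean, sd, *bounds)
            else:
                self._pmf_cache[key] = _rounded_normal_pmf(mean, sd)
        return self._pmf_cache[key]

    # -- survival ----------------------------------------------------------

    def base_survival(self, stage: str, t10: float) -> float:
        """Daily survival before dryness and density effects, clipped to [0,1]."""
        if stage == "egg":
            return float(np.clip(self.survival["egg"], 0.0, 1.0))
        cfg = self.survival[stage]
        if cfg["type"] == "constant":
            s = cfg["value"]
        elif cfg["type"] == "quadratic":
            s = _quadratic(t10, cfg["opt"], cfg["peak"], cfg["half_width"])
        else:
            raise ValueError(f"unknown survival type {cfg['type']!r}")
        return float(np.clip(s, 0.0, 1.0))

    def daily_survival(
        self,
        stage: str,
        t10: float,
        p10: float,
        stage_abundance: float,
        rain_effects: bool = True,
    ) -> float:
        """Daily survival with dryness penalty and linear density dependence.

        Larval and adult survival is multiplied by ``dry_penalty`` when the
        10-day mean precipitation falls below the dryness threshold
        (default 1 mm/day); egg and larval survival declines linearly with
        the stage's abundance.  Result clipped to [0, 1].
        """
        if stage_abundance < 0:
            raise ValueError("stage_abundance must be >= 0")
        s = self.base_survival(stage, t10)
        if (
            rain_effects
            and stage in ("larva", "adult")
            and p10 < self.survival["dry_threshold_mm"]
        ):
            s *= self.survival["dry_penalty"]
        if stage == "egg":
            s *= max(0.0, 1.0 - self.density_dependence["egg_slope"] * stage_abundance)
        elif stage == "larva":
            s *= max(0.0, 1.0 - self.density_dependence["larva_slope"] * stage_abundance)
        return float(np.clip(s, 0.0, 1.0))

    # -- reproduction ------------------------------------------------------

    def bloodmeal_p(self, t10: float, rh10: float) -> float:
        """Probability a female completing her cycle oviposits, in [0, 1]."""
        cfg = self.bloodmeal
        if cfg["type"] == "linear_humidity":
            p = cfg["intercept"] + cfg["slope"] * rh10
        elif cfg["type"] == "quadratic_temp":
            p = cfg["coeff"] * max(t10, 0.0) ** 2
        else:
            raise ValueError(f"unknown bloodmeal type {cfg['type']!r}")
        return float(np.clip(p, 0.0, 1.0))

    def eggs_mean(self, precip: float) -> float:
        cfg = self.eggs_per_batch
        return max(0.0, cfg["mean_intercept"] + cfg["mean_slope_per_mm"] * precip)


def _rounded_normal_pmf(mean: float, sd: float) -> np.ndarray:
    """PMF of round(Normal(mean, sd)) floored at 1 day, support 1.._MAX_DAYS."""
    if sd <= 0:
        d = int(np.clip(round(mean), 1, _MAX_DAYS))
        pmf = np.zeros(min(d, _MAX_DAYS) + 1)
        pmf[d] = 1.0
        return pmf
    hi = int(np.clip(np.ceil(mean + 6 * sd), 1, _MAX_DAYS))
    days = np.arange(hi + 1)
    upper = norm.cdf(days + 0.5, mean, sd)
    lower = norm.cdf(days - 0.5, mean, sd)
    pmf = upper - lower
    pmf[1] = upper[1]  # all mass below 1.5 rounds/floors to day 1
    pmf[0] = 0.0
    pmf[hi] += 1.0 - upper[hi]  # truncate the far tail onto the cap
    return pmf / pmf.sum()


def _rounded_truncnorm_pmf(mean: float, sd: float, lo: float, hi: float) -> np.ndarray:
    """PMF of round(TruncNormal(mean, sd; [lo, hi])), support 0..round(hi)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = truncnorm(a, b, loc=mean, scale=sd)
    d_lo, d_hi = int(round(lo)), int(round(hi))
    pmf = np.zeros(d_hi + 1)
    for d in range(d_lo, d_hi + 1):
        pmf[d] = dist.cdf(min(d + 0.5, hi)) - dist.cdf(max(d - 0.5, lo))
    return pmf / pmf.sum()


def available_species() -> list[str]:
    root = resources.files("mosqspec") / "species_data"
    return sorted(p.name.removesuffix(".yaml") for p in root.iterdir()
                  if p.name.endswith(".yaml"))


def load_species(name_or_path: str | Path) -> SpeciesParams:
    """Load a species parameter file by bundled name or explicit path."""
    path = Path(name_or_path)
    if path.suffix in (".yaml", ".yml") and path.exists():
        raw = yaml.safe_load(path.read_text())
    else:
        resource = resources.files("mosqspec") / "species_data" / f"{name_or_path}.yaml"
        if not resource.is_file():
            raise ValueError(
                f"unknown species {name_or_path!r}; bundled: {available_species()}"
            )
        raw = yaml.safe_load(resource.read_text())
    dev = raw["development"]
    return SpeciesParams(
        name=raw["name"],
        development={"embryo": dev["embryo"], "larva": dev["larva"]},
        stage_time_sd=dev.get("stage_time_sd", 1.0),
        temp_floor=dev.get("temp_floor", 1.0),
        gonotrophic=raw["gonotrophic"],
        survival=raw["survival"],
        density_dependence=raw["density_dependence"],
        bloodmeal=raw["bloodmeal"],
        eggs_per_batch=raw["eggs_per_batch"],
        female_fraction=raw.get("female_fraction", 0.5),
        overwinter_stage=raw["overwinter_stage"],
        diapause_temp=raw.get("diapause_temp", 10.0),
        hatch_rain_threshold_mm=raw.get("hatch_rain_threshold_mm"),
    )
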