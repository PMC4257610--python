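"""Stochastic individual-based life-cycle simulation of mosquito populations.

Three stages — egg, larva/pupa, adult — advance on a daily time step under
weather forcing.  Residence time in each immature stage is drawn at stage
entry from a normal distribution whose mean follows the temperature power
law d = A * T^(-a) (T the trailing 10-day mean temperature); adults run
repeated gonotrophic cycles until they die, each cycle ending in a
Bernoulli blood-meal/oviposition trial and, on success, a normally
distributed egg batch whose mean grows with rainfall.  Daily survival is
quadratic in temperature, penalised under dry spells (10-day mean
precipitation below 1 mm/day) and, for eggs and larvae, declines linearly
with crowding.

Individuals created on the same day in the same stage with the same sampled
residence time form one cohort; cohorts are thinned binomially each day,
which is statistically identical to per-individual simulation.  Internally
cohorts are stored as count arrays indexed by days-remaining, so a daily
step is a handful of vectorised draws.

Three forcing configurations separate exogenous from endogenous dynamics:
``full_weather`` (temperature + rainfall effects), ``temperature_only``
(rainfall effects on survival, oviposition and hatching turned off), and
``endogenous`` (constant temperature, default 18 degC, rainfall off).  An
optional observation layer converts true adult abundance into trap-style
observed counts through a rainfall-dependent activity fraction.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .species import _MAX_DAYS, SpeciesParams
from .timeseries import TimeSeries, WeatherSeries

__all__ = [
    "Cohort",
    "PopulationState",
    "IBSConfig",
    "IBSResult",
    "development_time",
    "gonotrophic_length",
    "daily_survival",
    "oviposition_success",
    "egg_batch",
    "step_day",
    "run_ibs",
    "apply_activity",
]

FORCINGS = ("full_weather", "temperature_only", "endogenous")


# ---------------------------------------------------------------------------
# sampling operations

def development_time(
    species: SpeciesParams,
    stage: str,
    t10: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Sample whole-day residence times: Normal(A*t10^-a, sd), rounded, floor 1."""
    mean = species.dev_mean(stage, t10)
    draws = np.rint(rng.normal(mean, species.stage_time_sd, size=size))
    return np.clip(draws, 1, _MAX_DAYS).astype(int) if size else int(
        np.clip(draws, 1, _MAX_DAYS)
    )


def gonotrophic_length(
    species: SpeciesParams,
    t10: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Sample whole-day gonotrophic-cycle lengths from the species distribution.

    With truncation bounds configured (Ae. vexans: [7, 13] around mean 10)
    draws are a truncated normal rounded to whole days; otherwise a normal
    around the temperature-dependent mean, floored at 1 day.
    """
    pmf = species.gono_pmf(t10)
    n = size or 1
    counts = rng.multinomial(n, pmf)
    draws = np.repeat(np.arange(len(pmf)), counts)
    rng.shuffle(draws)
    return draws if size else int(draws[0])


def daily_survival(
    species: SpeciesParams,
    stage: str,
    t10: float,
    p10: float,
    stage_abundance: float,
    rain_effects: bool = True,
) -> float:
    """Daily survival probability for one stage under current conditions."""
    return species.daily_survival(stage, t10, p10, stage_abundance, rain_effects)


def oviposition_success(
    species: SpeciesParams,
    t10: float,
    rh10: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Bernoulli blood-meal/oviposition trial(s) at the species' success rate."""
    if not 0.0 <= rh10 <= 100.0:
        raise ValueError("rh10 must be in [0, 100]")
    p = species.bloodmeal_p(t10, rh10)
    draws = rng.random(size=size) < p
    return draws if size else bool(draws)


def egg_batch(
    species: SpeciesParams,
    precip: float,
    rng: np.random.Generator,
    size: int | None = None,
):
    """Sample egg-batch sizes: Normal(mean(precip), sd), rounded, floor 0."""
    if precip < 0:
        raise ValueError("precip must be >= 0")
    mean = species.eggs_mean(precip)
    draws = np.rint(rng.normal(mean, species.eggs_per_batch["sd"], size=size))
    draws = np.clip(draws, 0, None)
    return draws.astype(int) if size else int(draws)


# ---------------------------------------------------------------------------
# population state

@dataclass
class Cohort:
    """Individuals sharing a stage, creation day and sampled residence time."""

    stage: str
    count: int
    days_remaining: int
    created_on: int = 0

    def __post_init__(self) -> None:
        if self.count < 0 or self.days_remaining < 0:
            raise ValueError("count and days_remaining must be >= 0")


@dataclass
class PopulationState:
    """Per-stage cohort bookkeeping of the population on one day.

    ``eggs``, ``larvae`` and ``adults`` are count arrays indexed by
    days-remaining until the next transition (gonotrophic completion for
    adults); ``ready_eggs`` holds embryonated floodwater eggs awaiting
    inundation.
    """

    day: int = 0
    eggs: np.ndarray = field(
        default_factory=lambda: np.zeros(_MAX_DAYS + 1, dtype=np.int64)
    )
    larvae: np.ndarray = field(
        default_factory=lambda: np.zeros(_MAX_DAYS + 1, dtype=np.int64)
    )
    adults: np.ndarray = field(
        default_factory=lambda: np.zeros(_MAX_DAYS + 1, dtype=np.int64)
    )
    ready_eggs: int = 0

    def validate(self) -> None:
        for name in ("eggs", "larvae", "adults"):
            if np.any(getattr(self, name) < 0):
                raise ValueError(f"negative cohort count in {name}")
        if self.ready_eggs < 0:
            raise ValueError("ready_eggs must be >= 0")

    @property
    def totals(self) -> dict[str, int]:
        return {
            "egg": int(self.eggs.sum()) + self.ready_eggs,
            "larva": int(self.larvae.sum()),
            "adult": int(self.adults.sum()),
        }

    @property
    def cohorts(self) -> list[Cohort]:
        out = []
        for stage, arr in (("egg", self.eggs), ("larva", self.larvae),
                           ("adult", self.adults)):
            for d in np.nonzero(arr)[0]:
                out.append(Cohort(stage, int(arr[d]), int(d), self.day))
        if self.ready_eggs:
            out.append(Cohort("egg", self.ready_eggs, 0, self.day))
        return out

    def is_empty(self) -> bool:
        return sum(self.totals.values()) == 0


@dataclass
class IBSConfig:
    """Configuration of one ensemble simulation."""

    species: SpeciesParams
    forcing: str = "full_weather"
    fixed_temp: float = 18.0
    fixed_rh: float = 70.0
    activity_on: bool = False
    activity_fn: Optional[Callable[[float], float]] = None
    activity_mode: str = "binomial"
    n_reps: int = 20
    n_days: int = 9 * 365
    init_count: int = 500
    burn_in: int = 365
    seed: int = 0

    def __post_init__(self) -> None:
        if self.forcing not in FORCINGS:
            raise ValueError(f"forcing must be one of {FORCINGS}")
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not 0 <= self.burn_in < self.n_days:
            raise ValueError("burn_in must lie in [0, n_days)")

    @property
    def rain_effects(self) -> bool:
        return self.forcing == "full_weather"


@dataclass
class _DayEnv:
    precip: float
    t10: float
    p10: float
    rh10: float
    rain_effects: bool


def _enter_stage(arr: np.ndarray, n: int, pmf: np.ndarray,
                 rng: np.random.Generator) -> None:
    if n <= 0:
        return
    counts = rng.multinomial(n, pmf)
    arr[: len(counts)] += counts


def _advance(
    state: PopulationState,
    species: SpeciesParams,
    env: _DayEnv,
    rng: np.random.Generator,
) -> None:
    """Advance the population by one day, in place.

    Order of operations: survival thinning per stage; development-clock
    decrement (frozen for the overwintering stage below the diapause
    temperature); stage transitions for cohorts reaching zero days (egg
    hatch gated by inundation for floodwater species); gonotrophic
    completions with oviposition, egg-batch creation and cycle renewal.
    """
    totals = state.totals
    # 1. survival thinning (binomial per cohort, vectorised over buckets)
    for stage, arr in (("egg", state.eggs), ("larva", state.larvae),
                       ("adult", state.adults)):
        s = species.daily_survival(
            stage, env.t10, env.p10, totals[stage], env.rain_effects
        )
        nz = np.nonzero(arr)[0]
        if len(nz):
            arr[nz] = rng.binomial(arr[nz], s)
    if state.ready_eggs:
        s = species.daily_survival(
            "egg", env.t10, env.p10, totals["egg"], env.rain_effects
        )
        state.ready_eggs = int(rng.binomial(state.ready_eggs, s))

    # 2. clock decrement; the overwintering stage freezes below diapause_temp
    diapause = env.t10 < species.diapause_temp
    completions: dict[str, int] = {}
    for stage, arr in (("egg", state.eggs), ("larva", state.larvae),
                       ("adult", state.adults)):
        frozen = diapause and stage == species.overwinter_stage
        if frozen:
            completions[stage] = 0
            continue
        completions[stage] = int(arr[0])
        arr[:-1] = arr[1:]
        arr[-1] = 0

    # 3. transitions
    hatch_gated = species.hatch_rain_threshold_mm is not None and env.rain_effects
    if hatch_gated:
        state.ready_eggs += completions["egg"]
        hatched = 0
        if env.precip >= species.hatch_rain_threshold_mm:
            hatched, state.ready_eggs = state.ready_eggs, 0
    else:
        hatched = completions["egg"] + state.ready_eggs
        state.ready_eggs = 0
    _enter_stage(state.larvae, hatched, species.development_pmf("larva", env.t10), rng)
    _enter_stage(state.adults, completions["larva"], species.gono_pmf(env.t10), rng)

    # 4. gonotrophic completions -> oviposition -> new egg cohorts;
    #    survivors start another cycle until they die
    n_complete = completions["adult"]
    if n_complete:
        p = species.bloodmeal_p(env.t10, env.rh10)
        successes = int(rng.binomial(n_complete, p))
        if successes:
            precip_eff = env.precip if env.rain_effects else 0.0
            mean = species.eggs_mean(precip_eff)
            sd = species.eggs_per_batch["sd"] * np.sqrt(successes)
            total_eggs = max(0, int(round(rng.normal(successes * mean, sd))))
            females = int(rng.binomial(total_eggs, species.female_fraction))
            _enter_stage(state.eggs, females,
                         species.development_pmf("embryo", env.t10), rng)
        _enter_stage(state.adults, n_complete, species.gono_pmf(env.t10), rng)
    state.day += 1


def step_day(
    state: PopulationState,
    species: SpeciesParams,
    env: dict | _DayEnv,
    rng: np.random.Generator,
    rain_effects: bool = True,
) -> PopulationState:
    """Pure single-day step: validate, copy, advance, return the new state."""
    state.validate()
    if isinstance(env, dict):
        env = _DayEnv(
            precip=env.get("precip", 0.0),
            t10=env["t10"],
            p10=env.get("p10", env.get("precip", 0.0)),
            rh10=env.get("rh10", 70.0),
            rain_effects=rain_effects,
        )
    new = copy.deepcopy(state)
    _advance(new, species, env, rng)
    return new


# ---------------------------------------------------------------------------
# ensemble runs

@dataclass
class IBSResult:
    """Ensemble output: per-replicate daily stage counts after burn-in."""

    dates: pd.DatetimeIndex
    adults: np.ndarray   # (n_reps, n_days)
    eggs: np.ndarray
    larvae: np.ndarray
    observed: Optional[np.ndarray]  # activity-filtered counts, or None
    config: IBSConfig

    def _series(self, matrix: np.ndarray, reduce: str, label: str) -> TimeSeries:
        stat = {"mean": np.mean, "min": np.min, "max": np.max}[reduce]
        return TimeSeries(self.dates, stat(matrix, axis=0), delta_t=1.0, label=label)

    def ensemble_mean(self, which: str = "adults") -> TimeSeries:
        return self._series(getattr(self, which), "mean", f"{which}.mean")

    def ensemble_min(self, which: str = "adults") -> TimeSeries:
        return self._series(getattr(self, which), "min", f"{which}.min")

    def ensemble_max(self, which: str = "adults") -> TimeSeries:
        return self._series(getattr(self, which), "max", f"{which}.max")

    def replicate_series(self, rep: int, which: str = "adults") -> TimeSeries:
        return TimeSeries(self.dates, getattr(self, which)[rep], delta_t=1.0,
                          label=f"{which}[{rep}]")


def _forcing_arrays(config: IBSConfig, weather: Optional[WeatherSeries]):
    n = config.n_days
    if config.forcing == "endogenous":
        temp = np.full(n, config.fixed_temp)
        precip = np.zeros(n)
        rh = np.full(n, config.fixed_rh)
        dates = pd.date_range("2004-01-01", periods=n, freq="D")
    else:
        if weather is None:
            raise ValueError(f"forcing={config.forcing!r} requires a WeatherSeries")
        if len(weather) < n:
            raise ValueError(
                f"weather has {len(weather)} days < n_days={n}"
            )
        temp = weather.temperature[:n]
        precip = weather.precipitation[:n].copy()
        rh = weather.relative_humidity[:n]
        dates = weather.dates[:n]
    t10 = pd.Series(temp).rolling(10, min_periods=1).mean().to_numpy()
    p10 = pd.Series(precip).rolling(10, min_periods=1).mean().to_numpy()
    rh10 = pd.Series(rh).rolling(10, min_periods=1).mean().to_numpy()
    return dates, temp, precip, rh, t10, p10, rh10


def _init_state(config: IBSConfig, t10_0: float,
                rng: np.random.Generator) -> PopulationState:
    state = PopulationState()
    species = config.species
    stage_arr = state.eggs if species.overwinter_stage == "egg" else state.larvae
    pmf = (
        species.development_pmf("embryo", t10_0)
        if species.overwinter_stage == "egg"
        else species.development_pmf("larva", t10_0)
    )
    _enter_stage(stage_arr, config.init_count, pmf, rng)
    return state


def run_ibs(config: IBSConfig, weather: Optional[WeatherSeries] = None) -> IBSResult:
    """Run ``n_reps`` independent replicates and collect daily stage counts.

    Replicate r is seeded with ``config.seed + r``, so the ensemble is
    bit-reproducible and replicates are independent.  The first ``burn_in``
    days are discarded from the returned arrays.  When ``activity_on``, an
    observed-count matrix is produced by binomially thinning true adult
    counts with the rainfall-driven activity fraction.
    """
    dates, _, precip, _, t10, p10, rh10 = _forcing_arrays(config, weather)
    n, b = config.n_days, config.burn_in
    shape = (config.n_reps, n - b)
    adults = np.zeros(shape, dtype=np.int64)
    eggs = np.zeros(shape, dtype=np.int64)
    larvae = np.zeros(shape, dtype=np.int64)
    rain = config.rain_effects
    for r in range(config.n_reps):
        rng = np.random.default_rng(config.seed + r)
        state = _init_state(config, t10[0], rng)
        for day in range(n):
            env = _DayEnv(precip[day], t10[day], p10[day], rh10[day], rain)
            _advance(state, config.species, env, rng)
            if day >= b:
                totals = state.totals
                adults[r, day - b] = totals["adult"]
                eggs[r, day - b] = totals["egg"]
                larvae[r, day - b] = totals["larva"]
    observed = None
    if config.activity_on:
        from .activity import parametric_activity

        fn = config.activity_fn or parametric_activity
        frac = np.clip([fn(x) for x in precip[b:]], 0.0, 1.0)
        obs_rng = np.random.default_rng(config.seed + config.n_reps + 1)
        if config.activity_mode == "binomial":
            observed = obs_rng.binomial(adults, frac[None, :])
        else:
            observed = np.rint(adults * frac[None, :]).astype(np.int64)
    return IBSResult(
        dates=pd.DatetimeIndex(dates[b:]),
        adults=adults,
        eggs=eggs,
        larvae=larvae,
        observed=observed,
        config=config,
    )


def apply_activity(
    adults: TimeSeries,
    precipitation: TimeSeries,
    activity_fn: Callable[[float], float],
    rng: np.random.Generator,
    mode: str = "binomial",
) -> TimeSeries:
    """Convert true adult abundance into trap-observed counts.

    Each day's observation is Binomial(adults_t, activity(precip_t))
    (``mode="binomial"``) or the rounded product (``mode="deterministic"``);
    the activity fraction is clipped to [0, 1].
    """
    if len(adults) != len(precipitation) or not (
        adults.dates == precipitation.dates
    ).all():
        raise ValueError("adult and precipitation series must share one calendar")
    if mode not in ("binomial", "deterministic"):
        raise ValueError("mode must be 'binomial' or 'deterministic'")
    frac = np.clip([activity_fn(x) for x in precipitation.values], 0.0, 1.0)
    counts = np.rint(adults.values).astype(np.int64)
    if np.any(counts < 0):
        raise ValueError("adult counts must be >= 0")
    if mode == "binomial":
        observed = rng.binomial(counts, frac)
    else:
        observed = np.rint(counts * frac)
    return adults.with_values(observed.astype(float),
                              label=f"{adults.label}.observed")
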