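import copy

import numpy as np
import pytest

from mosqspec import (
    IBSConfig,
    PopulationState,
    apply_activity,
    available_species,
    daily_survival,
    development_time,
    egg_batch,
    generate_weather,
    gonotrophic_length,
    load_species,
    oviposition_success,
    run_ibs,
    step_day,
)
from mosqspec.synthetic import WeatherGenParams


class TestSpeciesParams:
    def test_bundled_species_available(self):
        assert {"ae_vexans", "cs_melanura"} <= set(available_species())

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError, match="unknown species"):
            load_species("anopheles_nope")

    def test_power_law_exponents_positive(self, ae_vexans, cs_melanura):
        for sp in (ae_vexans, cs_melanura):
            for stage in ("embryo", "larva"):
                assert sp.development[stage]["A"] > 0
                assert sp.development[stage]["a"] > 0

    def test_survival_clipped_to_unit_interval(self, ae_vexans):
        for t in (-5.0, 0.0, 25.0, 60.0):
            for stage in ("egg", "larva", "adult"):
                assert 0.0 <= ae_vexans.base_survival(stage, t) <= 1.0


class TestDevelopmentTime:
    def test_mean_ratio_follows_power_law(self, ae_vexans):
        # d(10) / d(20) = 2^a exactly for the mean of the power law
        a = ae_vexans.development["embryo"]["a"]
        ratio = ae_vexans.dev_mean("embryo", 10.0) / ae_vexans.dev_mean("embryo", 20.0)
        assert ratio == pytest.approx(2.0**a, rel=1e-12)
        assert a == 1.90

    def test_sample_mean_matches_power_law(self, ae_vexans):
        rng = np.random.default_rng(0)
        n = 100_000
        draws = development_time(ae_vexans, "larva", 25.0, rng, size=n)
        mean = ae_vexans.dev_mean("larva", 25.0)
        se = ae_vexans.stage_time_sd / np.sqrt(n)
        # rounding to whole days adds at most ~0.1 d of bias
        assert abs(draws.mean() - mean) < 3 * se + 0.15

    def test_degenerate_sd_gives_deterministic_draws(self, ae_vexans):
        sp = copy.deepcopy(ae_vexans)
        sp.stage_time_sd = 0.0
        rng = np.random.default_rng(1)
        draws = development_time(sp, "embryo", 25.0, rng, size=100)
        assert len(np.unique(draws)) == 1
        assert draws[0] == round(sp.dev_mean("embryo", 25.0))

    def test_warmer_means_faster_development(self, ae_vexans, cs_melanura):
        rng = np.random.default_rng(2)
        for sp in (ae_vexans, cs_melanura):
            cold = development_time(sp, "larva", 16.0, rng, size=5000).mean()
            warm = development_time(sp, "larva", 24.0, rng, size=5000).mean()
            assert warm < cold


class TestGonotrophicCycle:
    def test_ae_vexans_draws_respect_truncation(self, ae_vexans):
        rng = np.random.default_rng(3)
        draws = gonotrophic_length(ae_vexans, 20.0, rng, size=50_000)
        assert draws.min() >= 7 and draws.max() <= 13

    def test_ae_vexans_mean_is_ten_days(self, ae_vexans):
        rng = np.random.default_rng(4)
        draws = gonotrophic_length(ae_vexans, 20.0, rng, size=100_000)
        se = draws.std() / np.sqrt(len(draws))
        assert abs(draws.mean() - 10.0) < 3 * se + 1e-3

    def test_cs_melanura_cycle_shortens_with_warmth(self, cs_melanura):
        rng = np.random.default_rng(5)
        warm = gonotrophic_length(cs_melanura, 26.0, rng, size=20_000).mean()
        cold = gonotrophic_length(cs_melanura, 16.0, rng, size=20_000).mean()
        assert warm < cold


class TestDailySurvival:
    def test_zero_crowding_wet_gives_base_rate(self, ae_vexans):
        s = daily_survival(ae_vexans, "larva", 22.0, p10=3.0, stage_abundance=0)
        assert s == pytest.approx(ae_vexans.base_survival("larva", 22.0))

    def test_dry_spell_penalises_survival(self, ae_vexans):
        dry = daily_survival(ae_vexans, "larva", 22.0, p10=0.5, stage_abundance=0)
        wet = daily_survival(ae_vexans, "larva", 22.0, p10=2.0, stage_abundance=0)
        assert dry < wet

    def test_crowding_floor_reaches_zero(self, ae_vexans):
        slope = ae_vexans.density_dependence["larva_slope"]
        s = daily_survival(ae_vexans, "larva", 22.0, p10=3.0,
                           stage_abundance=1.0 / slope)
        assert s == pytest.approx(0.0, abs=1e-12)

    def test_rain_effects_flag_disables_penalty(self, ae_vexans):
        off = daily_survival(ae_vexans, "larva", 22.0, p10=0.0,
                             stage_abundance=0, rain_effects=False)
        assert off == pytest.approx(ae_vexans.base_survival("larva", 22.0))


class TestOvipositionAndEggs:
    def test_humidity_raises_ae_vexans_success(self, ae_vexans):
        assert ae_vexans.bloodmeal_p(20.0, 90.0) > ae_vexans.bloodmeal_p(20.0, 40.0)

    def test_bernoulli_rate_matches_probability(self, cs_melanura):
        rng = np.random.default_rng(6)
        p = cs_melanura.bloodmeal_p(22.0, 70.0)
        draws = oviposition_success(cs_melanura, 22.0, 70.0, rng, size=100_000)
        se = np.sqrt(p * (1 - p) / len(draws))
        assert abs(draws.mean() - p) < 3 * se

    def test_zero_probability_never_succeeds(self, ae_vexans):
        sp = copy.deepcopy(ae_vexans)
        sp.bloodmeal = {"type": "linear_humidity", "intercept": 0.0, "slope": 0.0}
        rng = np.random.default_rng(7)
        assert not oviposition_success(sp, 20.0, 50.0, rng, size=1000).any()

    def test_egg_batch_mean_grows_with_rain(self, ae_vexans):
        assert ae_vexans.eggs_mean(10.0) > ae_vexans.eggs_mean(0.0)

    def test_egg_batch_monte_carlo_mean(self, ae_vexans):
        rng = np.random.default_rng(8)
        draws = egg_batch(ae_vexans, 5.0, rng, size=100_000)
        mean = ae_vexans.eggs_mean(5.0)
        se = ae_vexans.eggs_per_batch["sd"] / np.sqrt(len(draws))
        assert abs(draws.mean() - mean) < 3 * se + 0.5

    def test_degenerate_sd_deterministic_batch(self, ae_vexans):
        sp = copy.deepcopy(ae_vexans)
        sp.eggs_per_batch = dict(sp.eggs_per_batch, sd=0.0)
        rng = np.random.default_rng(9)
        draws = egg_batch(sp, 2.0, rng, size=50)
        assert len(np.unique(draws)) == 1


def _benign_species(base):
    """A copy with survival 1 and no density effects, for bookkeeping tests."""
    sp = copy.deepcopy(base)
    sp.survival = {
        "egg": 1.0,
        "larva": {"type": "constant", "value": 1.0},
        "adult": {"type": "constant", "value": 1.0},
        "dry_penalty": 1.0,
        "dry_threshold_mm": 1.0,
    }
    sp.density_dependence = {"egg_slope": 0.0, "larva_slope": 0.0}
    return sp


class TestStepDay:
    ENV = {"t10": 22.0, "p10": 3.0, "rh10": 70.0, "precip": 0.0}

    def test_empty_state_is_absorbing(self, ae_vexans):
        rng = np.random.default_rng(10)
        out = step_day(PopulationState(), ae_vexans, self.ENV, rng)
        assert out.is_empty()

    def test_counts_conserved_without_mortality_or_transitions(self, ae_vexans):
        sp = _benign_species(ae_vexans)
        state = PopulationState()
        state.eggs[5] = 100
        state.larvae[9] = 40
        state.adults[4] = 7
        rng = np.random.default_rng(11)
        out = step_day(state, sp, self.ENV, rng)
        assert out.totals == {"egg": 100, "larva": 40, "adult": 7}
        # clocks advanced by exactly one day
        assert out.eggs[4] == 100 and out.larvae[8] == 40 and out.adults[3] == 7

    def test_single_gonotrophic_completion_creates_one_egg_cohort(self, cs_melanura):
        sp = _benign_species(cs_melanura)
        sp.bloodmeal = {"type": "quadratic_temp", "coeff": 1.0}  # p clips to 1
        sp.eggs_per_batch = {"mean_intercept": 40.0, "mean_slope_per_mm": 0.0,
                             "sd": 0.0}
        sp.female_fraction = 1.0
        sp.stage_time_sd = 0.0  # one shared residence time -> one cohort
        sp._pmf_cache.clear()
        state = PopulationState()
        state.adults[0] = 1  # completes its cycle today
        rng = np.random.default_rng(12)
        out = step_day(state, sp, self.ENV, rng)
        assert out.totals["egg"] == 40   # one batch of eggs appears
        assert out.totals["adult"] == 1  # survivor starts a new cycle
        assert np.count_nonzero(out.eggs) == 1

    def test_inconsistent_state_rejected(self, ae_vexans):
        state = PopulationState()
        state.larvae[2] = -5
        with pytest.raises(ValueError, match="negative"):
            step_day(state, ae_vexans, self.ENV, np.random.default_rng(0))


class TestRunIBS:
    def test_zero_initial_population_stays_zero(self, cs_melanura):
        cfg = IBSConfig(species=cs_melanura, forcing="endogenous", n_reps=2,
                        n_days=400, init_count=0, seed=1)
        res = run_ibs(cfg)
        assert res.adults.sum() == 0 and res.eggs.sum() == 0

    def test_bit_reproducible_under_identical_seeds(self, cs_melanura):
        cfg = IBSConfig(species=cs_melanura, forcing="endogenous", n_reps=2,
                        n_days=500, seed=42)
        a = run_ibs(cfg)
        b = run_ibs(cfg)
        np.testing.assert_array_equal(a.adults, b.adults)
        c = run_ibs(IBSConfig(species=cs_melanura, forcing="endogenous",
                              n_reps=2, n_days=500, seed=43))
        assert not np.array_equal(a.adults, c.adults)

    def test_missing_weather_rejected_for_forced_configs(self, ae_vexans):
        cfg = IBSConfig(species=ae_vexans, forcing="full_weather", n_reps=1,
                        n_days=400)
        with pytest.raises(ValueError, match="requires a WeatherSeries"):
            run_ibs(cfg, weather=None)

    def test_endogenous_population_fluctuates_around_quasi_equilibrium(
        self, cs_melanura
    ):
        cfg = IBSConfig(species=cs_melanura, forcing="endogenous", n_reps=3,
                        n_days=4 * 365, seed=7)
        res = run_ibs(cfg)
        mean = res.ensemble_mean("adults").values
        # persists, bounded, and keeps fluctuating (no fixation, no blow-up)
        assert mean.mean() > 5
        assert mean.max() < 1e5
        last_two_years = mean[-730:]
        assert last_two_years.std() > 0.05 * last_two_years.mean()


class TestApplyActivity:
    def test_full_activity_is_identity(self, ts_factory):
        adults = ts_factory([10, 20, 30, 40.0])
        rain = ts_factory([0.0, 1.0, 2.0, 3.0])
        out = apply_activity(adults, rain, lambda p: 1.0,
                             np.random.default_rng(0), mode="deterministic")
        np.testing.assert_array_equal(out.values, adults.values)

    def test_zero_activity_gives_zeros(self, ts_factory):
        adults = ts_factory([10, 20, 30.0])
        rain = ts_factory([0.0, 1.0, 2.0])
        out = apply_activity(adults, rain, lambda p: 0.0,
                             np.random.default_rng(0))
        assert np.all(out.values == 0)

    def test_misaligned_series_rejected(self, ts_factory):
        adults = ts_factory([1.0, 2.0, 3.0])
        rain = ts_factory([0.0, 1.0, 2.0], start="2011-01-01")
        with pytest.raises(ValueError, match="calendar"):
            apply_activity(adults, rain, lambda p: 1.0, np.random.default_rng(0))

    def test_binomial_observation_bounded_by_population(self, ts_factory):
        adults = ts_factory([100.0] * 50)
        rng_rain = np.random.default_rng(1)
        rain = ts_factory(rng_rain.exponential(3.0, size=50))
        out = apply_activity(adults, rain, lambda p: 0.5,
                             np.random.default_rng(2))
        assert np.all(out.values <= 100) and np.all(out.values >= 0)


@pytest.fixture(scope="module")
def runs():
    weather = generate_weather(6 * 365, WeatherGenParams(seed=5))
    sp = load_species("cs_melanura")
    out = {}
    for forcing in ("endogenous", "temperature_only"):
        for act in (False, True):
            cfg = IBSConfig(species=sp, forcing=forcing, activity_on=act,
                            n_reps=3, n_days=6 * 365, seed=3)
            out[(forcing, act)] = run_ibs(
                cfg, weather=None if forcing == "endogenous" else weather
            )
    return out


class TestEnsembleForcingContrast:
    """Qualitative spectral chain across the three forcing configurations."""

    def _annual_power_fraction(self, ts):
        from mosqspec import power_spectrum

        spec = power_spectrum(ts, detrend="mean")
        annual = (spec.periods > 300) & (spec.periods < 450)
        return spec.power[annual].sum() / spec.power.sum()

    def test_seasonal_forcing_introduces_annual_peak(self, runs):
        endo = self._annual_power_fraction(
            runs[("endogenous", False)].ensemble_mean("adults"))
        forced = self._annual_power_fraction(
            runs[("temperature_only", False)].ensemble_mean("adults"))
        assert forced > 2 * endo

    def test_activity_flattens_spectrum_but_keeps_peak_position(self, runs):
        from mosqspec import find_peaks, power_spectrum

        res = runs[("temperature_only", False)]
        res_act = runs[("temperature_only", True)]
        plain = power_spectrum(res.replicate_series(0, "adults"), detrend="mean")
        observed = power_spectrum(
            res_act.replicate_series(0, "observed"), detrend="mean")

        def long_short_ratio(spec):
            longp = spec.power[spec.periods > 30].sum()
            shortp = spec.power[spec.periods <= 30].sum()
            return longp / shortp

        # activity boosts fast fluctuation relative to slow periodicities
        assert long_short_ratio(observed) < long_short_ratio(plain)
        # while the dominant long-period peak stays put (within a bin or two)
        p0 = find_peaks(plain, k=1, band=(60, 500))[0].period
        p1 = find_peaks(observed, k=1, band=(60, 500))[0].period
        assert abs(1 / p1 - 1 / p0) <= 2.5 / plain.n
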