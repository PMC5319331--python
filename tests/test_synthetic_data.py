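"""Ground-truth simulator: climate draws, life histories, censoring."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit

from sproutess.errors import InvalidArgumentError, MissingDataError
from sproutess.synthetic_data import (
    ClimateVarSpec,
    TrueParameterSet,
    censor_to_observed,
    gen_climate_series,
    grid_density,
    simulate_individuals,
    validate_life_history,
)
from sproutess.vital_rates import VitalRateSpec


def make_spec(coef, response="binomial", name="rate", year_sd=0.0):
    terms = tuple(k for k in coef if k != "intercept")
    return VitalRateSpec(name=name, response=response, terms=terms,
                         coef=dict(coef), year_sd=year_sd)


def simple_truth(surv=0.8, spr=0.7, **overrides):
    specs = {
        "survival": make_spec({"intercept": float(logit(surv))}),
        "sprouting": make_spec({"intercept": float(logit(spr))}),
        "growth": make_spec({"intercept": 0.7}, response="poisson"),
        "flowering": make_spec({"intercept": -1.0}),
        "flowers": make_spec({"intercept": 0.2}, response="poisson"),
    }
    cv = {"dt32": ClimateVarSpec(100.0, 10.0, "count"),
          "tpcp": ClimateVarSpec(1000.0, 100.0, "nonneg")}
    defaults = dict(specs=specs, climate_vars=cv, design="historical",
                    n0=100, max_size=9)
    defaults.update(overrides)
    return TrueParameterSet(**defaults)


class TestGenClimateSeries:
    def test_zero_sd_equals_mean_exactly(self):
        cv = {"temp": ClimateVarSpec(7.7, 0.0), "tpcp": ClimateVarSpec(1070.0, 0.0, "nonneg")}
        s = gen_climate_series(15, cv, seed=1)
        assert (s.data["temp"] == 7.7).all()
        assert (s.data["tpcp"] == 1070.0).all()

    def test_same_seed_identical(self):
        cv = {"temp": ClimateVarSpec(10.0, 2.0)}
        a = gen_climate_series(30, cv, seed=99)
        b = gen_climate_series(30, cv, seed=99)
        assert np.array_equal(a.data["temp"], b.data["temp"])

    def test_law_of_large_numbers(self):
        cv = {"tpcp": ClimateVarSpec(1000.0, 50.0, "nonneg")}
        s = gen_climate_series(10000, cv, seed=7)
        assert abs(s.data["tpcp"].mean() - 1000.0) < 3 * 50.0 / np.sqrt(10000)

    def test_counts_rounded_and_bounded(self):
        cv = {"dt32": ClimateVarSpec(5.0, 30.0, "count")}
        s = gen_climate_series(200, cv, seed=3)
        vals = s.data["dt32"]
        assert (vals == np.round(vals)).all()
        assert (vals >= 0).all() and (vals <= 366).all()

    def test_invalid_arguments(self):
        with pytest.raises(InvalidArgumentError):
            gen_climate_series(0, {"t": ClimateVarSpec(0, 1)}, seed=0)
        with pytest.raises(InvalidArgumentError):
            ClimateVarSpec(0.0, -1.0)


class TestSimulateIndividuals:
    def test_certain_survival_and_sprouting(self):
        truth = simple_truth(surv=0.999999, spr=0.999999, n0=30)
        clim = gen_climate_series(6, truth.climate_vars, seed=0)
        table = simulate_individuals(truth, clim, seed=1)
        counts = table.groupby("id").size()
        assert (counts == 6).all()
        assert (table["sprouted"] == 1).all()

    def test_zero_survival_kills_after_first_year(self):
        truth = simple_truth(surv=1e-9, n0=50)
        clim = gen_climate_series(5, truth.climate_vars, seed=0)
        table = simulate_individuals(truth, clim, seed=1)
        assert table["year"].max() == int(clim.years[0])

    def test_binomial_survival_oracle(self):
        p = 0.8
        truth = simple_truth(surv=p, spr=0.999999, n0=1200)
        clim = gen_climate_series(6, truth.climate_vars, seed=0)
        table = simulate_individuals(truth, clim, seed=5)
        # count survival transitions directly from the truth table
        trials = survived = 0
        last_year = int(clim.years[-1])
        for _, g in table.groupby("id"):
            years = set(g["year"])
            for t in sorted(years):
                if t < last_year:
                    trials += 1
                    survived += (t + 1) in years
        phat = survived / trials
        se = np.sqrt(p * (1 - p) / trials)
        assert abs(phat - p) < 2.58 * se  # 99% CI

    def test_missing_climate_year_raises(self):
        truth = simple_truth()
        clim = gen_climate_series(3, truth.climate_vars, seed=0)
        with pytest.raises(MissingDataError):
            simulate_individuals(truth, clim, seed=1, n_years=10)

    @pytest.mark.parametrize("seed", range(25))
    def test_random_parameterizations_satisfy_invariants(self, seed):
        rng = np.random.default_rng(seed)
        truth = simple_truth(
            surv=float(rng.uniform(0.3, 0.95)),
            spr=float(rng.uniform(0.3, 0.95)),
            n0=25, max_size=int(rng.integers(3, 10)),
        )
        truth.specs["growth"] = make_spec(
            {"intercept": float(rng.uniform(-0.5, 1.2))}, response="poisson")
        clim = gen_climate_series(5, truth.climate_vars, seed=seed)
        table = simulate_individuals(truth, clim, seed=seed + 1)
        if len(table):
            validate_life_history(table, truth.max_size)

    def test_positions_inside_plot(self):
        truth = simple_truth(n0=200, plot_extent=20.0)
        clim = gen_climate_series(3, truth.climate_vars, seed=0)
        table = simulate_individuals(truth, clim, seed=2)
        assert table["x"].between(0, 20).all()
        assert table["y"].between(0, 20).all()


class TestCensorToObserved:
    def toy_truth(self, rows):
        return pd.DataFrame(rows, columns=["id", "year", "alive", "sprouted", "size",
                                           "flowering", "flowers", "fruits", "x", "y"])

    def test_always_sprouting_equals_truth(self):
        truth = self.toy_truth([(1, y, 1, 1, 2, 0, 0, 0, 1.0, 1.0)
                                for y in range(2000, 2005)])
        obs = censor_to_observed(truth, study_end=2004)
        common = ["id", "year", "sprouted", "size"]
        pd.testing.assert_frame_equal(obs[common].reset_index(drop=True),
                                      truth[common].reset_index(drop=True))
        assert not obs["ambiguous"].any()

    def test_interior_gap_reconstructed_as_dormant(self):
        truth = self.toy_truth([
            (1, 2000, 1, 1, 2, 0, 0, 0, 1.0, 1.0),
            (1, 2001, 1, 0, 0, 0, 0, 0, 1.0, 1.0),
            (1, 2002, 1, 1, 3, 0, 0, 0, 1.0, 1.0),
        ])
        obs = censor_to_observed(truth, study_end=2002)
        mid = obs[obs["year"] == 2001].iloc[0]
        assert mid["alive"] == 1 and mid["sprouted"] == 0 and mid["size"] == 0

    def test_terminal_dormancy_of_k_years_is_ambiguous(self):
        # dormant through the final 3 years with k = 3: dead-or-dormant
        truth = self.toy_truth(
            [(1, 2000, 1, 1, 2, 0, 0, 0, 1.0, 1.0),
             (1, 2001, 1, 1, 2, 0, 0, 0, 1.0, 1.0)]
            + [(1, y, 1, 0, 0, 0, 0, 0, 1.0, 1.0) for y in (2002, 2003, 2004)]
        )
        obs = censor_to_observed(truth, study_end=2004, k_ambiguous=3)
        assert obs["year"].max() == 2001
        assert bool(obs.iloc[-1]["ambiguous"])
        # the ambiguous tail contributes no survival response rows
        from sproutess.vital_rates import build_design
        from sproutess.climate_forecast import ClimateSeries
        from sproutess.errors import EmptyDesignError

        clim = ClimateSeries(pd.DataFrame({"dt32": [100.0] * 8, "tpcp": [1000.0] * 8},
                                          index=list(range(1999, 2007))))
        with pytest.raises(EmptyDesignError):
            # the only candidate row (2001) is excluded by the ambiguous flag
            build_design(obs, clim, "historical", "survival", study_end=2004)

    def test_long_terminal_gap_classified_dead(self):
        truth = self.toy_truth(
            [(1, y, 1, 1, 2, 0, 0, 0, 1.0, 1.0) for y in (2000, 2001)]
        )
        obs = censor_to_observed(truth, study_end=2010, k_ambiguous=3)
        assert obs["year"].max() == 2001
        assert not obs["ambiguous"].any()  # observer records a death

    def test_never_seen_individual_dropped(self):
        truth = self.toy_truth([(1, 2000, 1, 0, 0, 0, 0, 0, 1.0, 1.0)])
        obs = censor_to_observed(truth, study_end=2000)
        assert len(obs) == 0


class TestGridDensity:
    def test_three_in_one_cell(self):
        d = grid_density(np.array([0.1, 0.5, 0.9]), np.array([0.2, 0.3, 0.4]))
        assert (d == 3).all()

    def test_half_open_boundary_rule(self):
        # x = 1.0 belongs to cell [1, 2)
        d = grid_density(np.array([0.99, 1.0]), np.array([0.5, 0.5]))
        assert (d == 1).all()

    def test_toy_layout_hand_tally(self):
        x = np.array([0.2, 0.8, 1.5, 1.6, 3.2])
        y = np.array([0.2, 0.9, 0.5, 0.1, 2.0])
        # cells: (0,0) x2, (1,0) x2, (3,2) x1
        assert grid_density(x, y).tolist() == [2.0, 2.0, 2.0, 2.0, 1.0]


class TestEmpiricalRatesMatchLinkInverse:
    def test_sprouting_rate_converges_to_logistic(self):
        """Monte-Carlo per-year sprouting fraction matches the link-inverted
        linear predictor within 3 standard errors."""
        p_spr = 0.65
        truth = simple_truth(surv=0.97, spr=p_spr, n0=3000)
        clim = gen_climate_series(3, truth.climate_vars, seed=0)
        table = simulate_individuals(truth, clim, seed=9)
        last = table[table["year"] == int(clim.years[-1])]
        phat = last["sprouted"].mean()
        se = np.sqrt(p_spr * (1 - p_spr) / len(last))
        assert abs(phat - p_spr) < 3 * se
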