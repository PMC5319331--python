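"""Synthetic species-analogue model bundles.

Three desk-scale demographic models mirror the fitted sign structures of
the three study populations, each with a constructed trade-off between
sprouting, growth and survival that yields an interior, convergence-stable
optimum of the sprouting intercept, and a climate sensitivity with a known
sign:

* ``parviflorum_analogue`` (historical design) -- survival falls with
  emergent size, more steeply the more winter frost days there are; large
  plants are dormancy-prone and dormancy is a survival refuge that
  preserves stored size (growth depends on the previous year's size).
  A warming scenario (declining frost days) cheapens emergence, so the
  optimal sprouting deviation trends upward.
* ``candidum_analogue`` (historical design) -- the same refuge structure,
  but the emergent-size cost is amplified by annual precipitation; the
  scenario's precipitation excursion (rise and return) pushes the optimum
  down and back, so the trajectory returns near its starting value.
* ``ophrys_analogue`` (age x stage design) -- mortality rises steeply
  with size (flowering partly rescues it), growth ratchets size upward
  while the plant stays emergent and dormancy is the only reset;
  reproduction is concentrated in small plants.  Rising spring
  precipitation deepens the size cost, so the optimum trends downward.

Density regulation acts on sprouting (juvenile emergence) in the two
historical analogues and on adult survival in the age x stage analogue.

These are fixtures with constructed parameters, not fitted estimates:
trade-off coefficients, juvenile parameters and plateau targets are
package defaults chosen so each fixture grows at mean climate
(lambda_0 > 1), supports Ricker calibration, and has its ESS inside the
default search bounds.
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .climate_forecast import ClimateSeries
from .life_cycle import (
    default_juvenile_params,
    toy_agestage_space,
    toy_historical_space,
)
from .matrix_builder import DemographicModel, FecundityParams
from .synthetic_data import ClimateVarSpec, TrueParameterSet
from .vital_rates import VitalRateSpec

_YEAR_SD = {"survival": 0.25, "sprouting": 0.25, "growth": 0.08,
            "flowering": 0.15, "flowers": 0.10}


def _spec(name, response, coef, year_sd=0.0):
    terms = tuple(k for k in coef if k != "intercept")
    return VitalRateSpec(name=name, response=response, terms=terms,
                         coef=dict(coef), year_sd=year_sd)


@dataclass
class Analogue:
    """One species-analogue fixture: model bundle, generating truth,
    climate scenario, calibration target and expected trait trend."""

    name: str
    model: DemographicModel
    truth: TrueParameterSet
    scenario: Callable[..., ClimateSeries]
    plateau_target: float
    dd_rate: str
    dd_on_adults: bool
    expected_trend: str  # "up" | "return" | "down"

    def density_truth(self, slope: float | None = None) -> TrueParameterSet:
        """Generating parameters with a negative density effect on the
        analogue's density-dependent rate (for screening fixtures)."""
        truth = deepcopy(self.truth)
        rate = self.dd_rate
        if slope is None:
            slope = -0.25 if rate == "sprouting" else -0.15
        s = truth.specs[rate]
        truth.specs[rate] = _spec(s.name, s.response,
                                  {**s.coef, "density": slope}, s.year_sd)
        return truth


def gavin_scenario(tpcp_amplitude: float = 0.0, excursion_fraction: float = 0.6):
    """Deterministic warming scenario for the historical analogues: winter
    frost days decline linearly (115 -> 70); annual precipitation makes a
    sinusoidal excursion of the given amplitude (mm) over the first
    ``excursion_fraction`` of the horizon and then sits back at its
    baseline (so trailing running-mean windows clear the excursion)."""

    def make(n_years: int = 80, start_year: int = 2020) -> ClimateSeries:
        years = np.arange(start_year, start_year + n_years)
        frac = (years - years[0]) / max(n_years - 1, 1)
        dt32 = 115.0 - 45.0 * frac
        phase = np.clip(frac / excursion_fraction, 0.0, 1.0)
        tpcp = 1070.0 + tpcp_amplitude * np.sin(np.pi * phase)
        return ClimateSeries(pd.DataFrame({"dt32": dt32, "tpcp": tpcp}, index=years),
                             provenance="simulated")

    return make


def castlehill_scenario():
    """Deterministic wetting scenario for the age x stage analogue: spring
    precipitation rises linearly (330 -> 450 mm), sunshine stays flat."""

    def make(n_years: int = 80, start_year: int = 2020) -> ClimateSeries:
        years = np.arange(start_year, start_year + n_years)
        frac = (years - years[0]) / max(n_years - 1, 1)
        sun = np.full(len(years), 202.0)
        sprppt = 330.0 + 120.0 * frac
        return ClimateSeries(pd.DataFrame({"sun": sun, "sprppt": sprppt}, index=years),
                             provenance="simulated")

    return make


def _historical_bundle(name, survival_coef):
    space = toy_historical_space(max_size=4)
    climate_vars = {
        "dt32": ClimateVarSpec(110.0, 12.0, "count"),
        "tpcp": ClimateVarSpec(1070.0, 140.0, "nonneg"),
    }
    specs = {
        "survival": _spec("survival", "binomial", survival_coef, _YEAR_SD["survival"]),
        "sprouting": _spec("sprouting", "binomial",
                           {"intercept": 0.6, "siz_t": -0.6}, _YEAR_SD["sprouting"]),
        "growth": _spec("growth", "poisson",
                        {"intercept": 0.2, "siz_t": 0.3, "siz_t1": 0.4},
                        _YEAR_SD["growth"]),
        "flowering": _spec("flowering", "binomial",
                           {"intercept": 1.0, "siz_next": -0.4}, _YEAR_SD["flowering"]),
        "flowers": _spec("flowers", "poisson", {"intercept": 0.3}, _YEAR_SD["flowers"]),
    }
    fec = FecundityParams(seeds_per_fruit=4000.0, germination=0.002,
                          protocorm_to_seedling=0.45, fruit_set=0.35)
    model = DemographicModel(
        space=space, specs=specs, fecundity=fec,
        juveniles=default_juvenile_params(space),
        climate_vars=climate_vars, plot_area=400.0,
    )
    truth = TrueParameterSet(
        specs=specs, climate_vars=climate_vars, design="historical",
        n0=300, recruits_per_year=12, max_size=space.max_size,
        plot_extent=20.0, plateau_level=0.8,
    )
    return model, truth


def parviflorum_analogue() -> Analogue:
    """Historical-design analogue whose optimum rises under warming."""
    survival = {
        "intercept": 3.2, "siz_t": -0.39, "siz_t:flwyn_t": 0.3,
        "dt32": -0.004, "siz_t:dt32": -0.003,
    }
    model, truth = _historical_bundle("parviflorum", survival)
    return Analogue(
        name="parviflorum", model=model, truth=truth,
        scenario=gavin_scenario(tpcp_amplitude=0.0),
        plateau_target=0.8, dd_rate="sprouting", dd_on_adults=False,
        expected_trend="up",
    )


def candidum_analogue() -> Analogue:
    """Historical-design analogue whose optimum dips with the
    precipitation excursion and returns near its start."""
    survival = {
        "intercept": 3.2, "siz_t": -0.28, "siz_t:flwyn_t": 0.3,
        "dt32": -0.004, "siz_t:tpcp": -0.0004,
    }
    model, truth = _historical_bundle("candidum", survival)
    return Analogue(
        name="candidum", model=model, truth=truth,
        scenario=gavin_scenario(tpcp_amplitude=220.0),
        plateau_target=0.8, dd_rate="sprouting", dd_on_adults=False,
        expected_trend="return",
    )


def ophrys_analogue() -> Analogue:
    """Age x stage analogue whose optimum declines under wetting."""
    space = toy_agestage_space(max_size=3, max_age=4)
    climate_vars = {
        "sun": ClimateVarSpec(202.0, 6.0, "nonneg"),
        "sprppt": ClimateVarSpec(350.0, 40.0, "nonneg"),
    }
    specs = {
        "survival": _spec("survival", "binomial", {
            "intercept": 3.7, "siz_t": -0.9, "siz_t:flwyn_t": 0.3,
            "age": -0.05, "sprppt": -0.0008, "siz_t:sprppt": -0.0008,
        }, _YEAR_SD["survival"]),
        "sprouting": _spec("sprouting", "binomial",
                           {"intercept": 0.237, "siz_t": -0.7}, _YEAR_SD["sprouting"]),
        "growth": _spec("growth", "poisson",
                        {"intercept": -0.6, "siz_t": 0.8, "sprppt": 0.0015},
                        _YEAR_SD["growth"]),
        "flowering": _spec("flowering", "binomial",
                           {"intercept": 1.5, "siz_next": -1.3, "sprppt": 0.0008},
                           _YEAR_SD["flowering"]),
        "flowers": _spec("flowers", "poisson",
                         {"intercept": 0.3, "siz_t": 0.2}, _YEAR_SD["flowers"]),
    }
    fec = FecundityParams(seeds_per_fruit=3000.0, germination=0.0045,
                          protocorm_to_seedling=0.5, fruit_set=0.35)
    model = DemographicModel(
        space=space, specs=specs, fecundity=fec,
        juveniles=default_juvenile_params(space),
        climate_vars=climate_vars, plot_area=400.0,
    )
    truth = TrueParameterSet(
        specs=specs, climate_vars=climate_vars, design="agestage",
        n0=300, recruits_per_year=12, max_size=space.max_size,
        plot_extent=20.0, plateau_level=0.6,
    )
    return Analogue(
        name="ophrys", model=model, truth=truth,
        scenario=castlehill_scenario(),
        plateau_target=0.6, dd_rate="survival", dd_on_adults=True,
        expected_trend="down",
    )


def all_analogues() -> list[Analogue]:
    return [parviflorum_analogue(), candidum_analogue(), ophrys_analogue()]


def calibrated_model(analogue: Analogue) -> DemographicModel:
    """The analogue's model with its Ricker modifier calibrated to the
    plateau target at mean climate."""
    from .density_dependence import calibrate_ricker

    params = calibrate_ricker(
        analogue.model, analogue.plateau_target, rate=analogue.dd_rate,
        on_adults=analogue.dd_on_adults,
    )
    return analogue.model.with_dd(params)
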