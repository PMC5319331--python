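"""Ground-truth simulator for climate series and individual life histories.

Every downstream stage (vital-rate fitting, matrix assembly, density
calibration, adaptive dynamics, forecasting) is testable against data
generated here with known parameters.  The simulator draws each
individual's yearly fate in the conditional order

    survival -> sprouting -> size (truncated Poisson, 1..max, given
    sprouting) -> flowering -> flower count (-> fruiting -> fruit count
    where configured),

with covariates taken from the individual's current state, its previous
year's state (historical design) or its age (age x stage design), the
year's climate, and optionally local density; a per-year random intercept
on each rate is shared by all individuals in that year.

All randomness flows from one master seed through a
``numpy.random.SeedSequence`` spawning scheme, so each stage is
independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .climate_forecast import ClimateSeries
from .errors import InvalidArgumentError, MissingDataError
from .vital_rates import VitalRateSpec

TABLE_COLUMNS = [
    "id", "year", "alive", "sprouted", "size", "flowering",
    "flowers", "fruits", "x", "y",
]


@dataclass(frozen=True)
class ClimateVarSpec:
    """Marginal distribution of one climate variable.

    ``kind`` is ``"normal"`` (unbounded), ``"nonneg"`` (normal truncated
    at 0, e.g. precipitation) or ``"count"`` (rounded and clipped to
    [0, 366], e.g. frost days).
    """

    mean: float
    sd: float
    kind: str = "normal"

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise InvalidArgumentError("climate sd must be >= 0")
        if self.kind not in ("normal", "nonneg", "count"):
            raise InvalidArgumentError(f"unknown climate kind {self.kind!r}")


@dataclass
class TrueParameterSet:
    """Generating parameters for a synthetic population.

    ``specs`` holds one :class:`~sproutess.vital_rates.VitalRateSpec` per
    vital rate with the *true* coefficients (same term structure as the
    fitted models).  ``plateau_level`` is the carrying level in adults per
    plot that density calibration targets on this population's fixtures.
    """

    specs: dict[str, VitalRateSpec]
    climate_vars: dict[str, ClimateVarSpec]
    design: str = "historical"
    n0: int = 200
    recruits_per_year: int = 0
    max_size: int = 9
    max_flowers: int = 8
    plot_extent: float = 20.0
    init_size_mean: float = 2.0
    init_flower_prob: float = 0.3
    plateau_level: float = 400.0

    def __post_init__(self) -> None:
        if self.n0 < 1:
            raise InvalidArgumentError("initial population size must be >= 1")
        if self.design not in ("historical", "agestage"):
            raise InvalidArgumentError(f"unknown design {self.design!r}")
        for key in ("survival", "sprouting", "growth", "flowering"):
            if key not in self.specs:
                raise InvalidArgumentError(f"missing vital-rate spec {key!r}")

    @property
    def uses_density(self) -> bool:
        return any(
            part == "density"
            for s in self.specs.values()
            for term in s.terms
            for part in term.split(":")
        )


def gen_climate_series(
    n_years: int,
    variable_specs: dict[str, ClimateVarSpec],
    seed: int,
    start_year: int = 2000,
) -> ClimateSeries:
    """Draw independent per-year values for each climate variable.

    Variables are independent normals by default (the study systems give
    only marginal distributions); precipitation-like variables are
    truncated at 0, count variables rounded.  Reproducible given seed.
    """
    if n_years < 1:
        raise InvalidArgumentError("n_years must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    years = np.arange(start_year, start_year + n_years)
    data = {}
    for name, vs in variable_specs.items():
        vals = rng.normal(vs.mean, vs.sd, size=n_years) if vs.sd > 0 else np.full(n_years, vs.mean)
        if vs.kind == "nonneg":
            vals = np.clip(vals, 0.0, None)
        elif vs.kind == "count":
            vals = np.clip(np.round(vals), 0, 366)
        data[name] = vals
    return ClimateSeries(pd.DataFrame(data, index=years), provenance="simulated")


def _truncated_poisson(rng, mu: np.ndarray, kmax: int, n: int | None = None) -> np.ndarray:
    """Vectorized draw from Poisson(mu) truncated to {1..kmax}."""
    mu = np.atleast_1d(np.asarray(mu, float))
    if n is not None and mu.shape != (n,):
        mu = np.broadcast_to(mu, (n,)).copy()
    mu = np.clip(mu, 1e-12, 1e6)
    ks = np.arange(1, kmax + 1, dtype=float)
    logpmf = ks[:, None] * np.log(mu)[None, :] - mu[None, :] - np.cumsum(np.log(ks))[:, None]
    pmf = np.exp(logpmf - logpmf.max(axis=0, keepdims=True))
    cdf = np.cumsum(pmf, axis=0)
    cdf /= cdf[-1]
    u = rng.random(len(mu))
    return 1 + (u[None, :] > cdf).sum(axis=0)


def grid_density(x: np.ndarray, y: np.ndarray, cell: float = 1.0) -> np.ndarray:
    """Individuals per grid cell, assigned back to each individual.

    Cells are half-open ``[x, x + cell)`` so boundary assignment is
    deterministic.  With a 1 m cell the count is individuals per m^2.
    """
    cx = np.floor(np.asarray(x) / cell).astype(int)
    cy = np.floor(np.asarray(y) / cell).astype(int)
    keys = cx * 1_000_003 + cy
    uniq, inv, counts = np.unique(keys, return_inverse=True, return_counts=True)
    return counts[inv].astype(float)


def _year_covariates(clim_row: dict, size_t, flw_t, size_p, flw_p, age, density):
    cov = {
        "siz_t": size_t.astype(float),
        "flwyn_t": flw_t.astype(float),
        "siz_t1": size_p.astype(float),
        "flwyn_t1": flw_p.astype(float),
        "grw_t": (size_t - size_p).astype(float),
        "age": age.astype(float),
    }
    if density is not None:
        cov["density"] = density
    n = len(size_t)
    for k, v in clim_row.items():
        cov[k] = np.full(n, float(v))
    return cov


def simulate_individuals(
    params: TrueParameterSet,
    climate: ClimateSeries,
    seed: int,
    n_years: int | None = None,
) -> pd.DataFrame:
    """Simulate a full (uncensored) life-history table.

    The returned table has one row per individual-year while alive; a
    vegetatively dormant year is an alive row with ``sprouted=0`` and size
    0.  Dead individuals have no later rows.
    """
    years = [int(y) for y in climate.years]
    if n_years is not None:
        if n_years > len(years):
            raise MissingDataError("climate series shorter than requested simulation")
        years = years[:n_years]
    if len(years) < 1:
        raise MissingDataError("empty climate series")

    ss = np.random.SeedSequence(seed)
    rng_init, rng_step = [np.random.default_rng(s) for s in ss.spawn(2)]

    fruiting = "fruiting" in params.specs

    def init_state(n, rng):
        size = _truncated_poisson(rng, np.full(n, params.init_size_mean), params.max_size)
        flw = rng.random(n) < params.init_flower_prob
        return size, flw

    n0 = params.n0
    ids = np.arange(n0)
    next_id = n0
    x = rng_init.uniform(0, params.plot_extent, n0)
    y = rng_init.uniform(0, params.plot_extent, n0)
    size_t, flw_t = init_state(n0, rng_init)
    sprouted_t = np.ones(n0, bool)
    size_p, flw_p = size_t.copy(), flw_t.copy()   # no pre-study history: zero growth
    first_year = np.full(n0, years[0])

    rows: list[pd.DataFrame] = []

    def emit(year, ids_, spr, size, flw, flowers, fruits, x_, y_):
        rows.append(pd.DataFrame({
            "id": ids_, "year": year, "alive": 1,
            "sprouted": spr.astype(int), "size": np.where(spr, size, 0),
            "flowering": (spr & flw).astype(int),
            "flowers": np.where(spr & flw, flowers, 0),
            "fruits": np.where(spr & flw, fruits, 0),
            "x": x_, "y": y_,
        }))

    def draw_reproduction(rng, cov, flw_mask, year_devs):
        flowers = np.zeros(len(flw_mask), int)
        fruits = np.zeros(len(flw_mask), int)
        if flw_mask.any():
            sub = {k: v[flw_mask] for k, v in cov.items()}
            mu = np.exp(params.specs["flowers"].linear_predictor(
                sub, year_dev=year_devs["flowers"])) if "flowers" in params.specs else np.full(flw_mask.sum(), 1.0)
            fl = _truncated_poisson(rng, mu, params.max_flowers, n=int(flw_mask.sum()))
            flowers[flw_mask] = fl
            if fruiting:
                sub["flw_t"] = fl.astype(float)
                p_fr = expit(params.specs["fruiting"].linear_predictor(
                    sub, year_dev=year_devs["fruiting"]))
                fru = rng.random(len(fl)) < p_fr
                n_fr = np.zeros(len(fl), int)
                if fru.any():
                    sub2 = {k: v[fru] for k, v in sub.items()}
                    mu_f = np.exp(params.specs["fruits"].linear_predictor(
                        sub2, year_dev=year_devs["fruits"]))
                    n_fr[fru] = _truncated_poisson(rng, mu_f, params.max_flowers, n=int(fru.sum()))
                fruits[flw_mask] = n_fr
        return flowers, fruits

    def draw_devs(rng):
        return {k: (rng.normal(0.0, s.year_sd) if s.year_sd > 0 else 0.0)
                for k, s in params.specs.items()}

    # year 0: reproduction state for the initial population
    devs0 = draw_devs(rng_step)
    clim0 = climate.year_values(years[0])
    dens0 = grid_density(x, y) if params.uses_density else None
    cov0 = _year_covariates(clim0, size_t, flw_t.astype(float), size_p,
                            flw_p.astype(float), np.ones(n0), dens0)
    flowers0, fruits0 = draw_reproduction(rng_step, cov0, flw_t & sprouted_t, devs0)
    emit(years[0], ids, sprouted_t, size_t, flw_t, flowers0, fruits0, x, y)

    for t, t_next in zip(years[:-1], years[1:]):
        if t_next not in climate.data.index:
            raise MissingDataError(f"climate year {t_next} missing")
        n = len(ids)
        if n == 0 and params.recruits_per_year == 0:
            break
        devs = draw_devs(rng_step)
        clim_next = climate.year_values(t_next)
        density = grid_density(x, y) if params.uses_density else None
        age = (t - first_year + 1).astype(float)
        cov = _year_covariates(clim_next, size_t, flw_t.astype(float),
                               size_p, flw_p.astype(float), age, density)

        p_surv = expit(params.specs["survival"].linear_predictor(cov, year_dev=devs["survival"]))
        alive = rng_step.random(n) < p_surv
        p_spr = expit(params.specs["sprouting"].linear_predictor(cov, year_dev=devs["sprouting"]))
        spr = alive & (rng_step.random(n) < p_spr)

        new_size = np.zeros(n, int)
        new_flw = np.zeros(n, bool)
        if spr.any():
            sub = {k: v[spr] for k, v in cov.items()}
            mu = np.exp(params.specs["growth"].linear_predictor(sub, year_dev=devs["growth"]))
            drawn = _truncated_poisson(rng_step, mu, params.max_size, n=int(spr.sum()))
            new_size[spr] = drawn
            sub["siz_next"] = drawn.astype(float)
            p_flw = expit(params.specs["flowering"].linear_predictor(
                sub, year_dev=devs["flowering"]))
            new_flw[spr] = rng_step.random(spr.sum()) < p_flw

        # survivors advance; reproduction is drawn in the new year's state
        keep = alive
        ids, x, y = ids[keep], x[keep], y[keep]
        first_year = first_year[keep]
        size_p, flw_p = size_t[keep], flw_t[keep]
        size_t, flw_t = new_size[keep], new_flw[keep]
        sprouted_t = spr[keep]

        # recruits enter as sprouting adults
        r = params.recruits_per_year
        if r > 0:
            rid = np.arange(next_id, next_id + r)
            next_id += r
            rx = rng_step.uniform(0, params.plot_extent, r)
            ry = rng_step.uniform(0, params.plot_extent, r)
            rs, rf = init_state(r, rng_step)
            ids = np.concatenate([ids, rid])
            x, y = np.concatenate([x, rx]), np.concatenate([y, ry])
            first_year = np.concatenate([first_year, np.full(r, t_next)])
            size_p = np.concatenate([size_p, rs])
            flw_p = np.concatenate([flw_p, rf])
            size_t = np.concatenate([size_t, rs])
            flw_t = np.concatenate([flw_t, rf])
            sprouted_t = np.concatenate([sprouted_t, np.ones(r, bool)])

        if len(ids):
            dens_next = grid_density(x, y) if params.uses_density else None
            age_next = (t_next - first_year + 1).astype(float)
            cov_next = _year_covariates(clim_next, size_t, flw_t.astype(float),
                                        size_p, flw_p.astype(float), age_next, dens_next)
            flowers, fruits = draw_reproduction(
                rng_step, cov_next, flw_t & sprouted_t, devs)
            emit(t_next, ids, sprouted_t, size_t, flw_t, flowers, fruits, x, y)

    table = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=TABLE_COLUMNS)
    table = table.sort_values(["id", "year"]).reset_index(drop=True)
    if params.uses_density:
        table = attach_density(table)
    return table


def attach_density(table: pd.DataFrame, cell: float = 1.0) -> pd.DataFrame:
    """Add a per-row local density column (individuals per cell per year)."""
    out = table.copy()
    dens = np.zeros(len(out))
    for _, idx in out.groupby("year").indices.items():
        dens[idx] = grid_density(out["x"].to_numpy()[idx], out["y"].to_numpy()[idx], cell)
    out["density"] = dens
    return out


def censor_to_observed(
    truth: pd.DataFrame,
    study_end: int | None = None,
    k_ambiguous: int = 3,
) -> pd.DataFrame:
    """Reduce a truth table to the observer's view.

    Dormant years are unobservable in the field; interior gaps between
    emergences are reconstructed as dormancy.  After an individual's last
    emergence: a terminal unseen gap of 1..``k_ambiguous`` years through
    the study end leaves the plant dead-or-dormant (flagged ``ambiguous``
    on its final row, excluding it from survival responses); a longer gap
    leads the observer to classify the plant as dead in the year after
    last emergence (even if it was truly dormant for part of the gap).
    Individuals never seen above ground are dropped entirely.
    """
    if study_end is None:
        study_end = int(truth["year"].max())
    out_rows = []
    for ind, g in truth.sort_values(["id", "year"]).groupby("id", sort=False):
        g = g[g["year"] <= study_end]
        seen = g[g["sprouted"] == 1]
        if seen.empty:
            continue
        first_e, last_e = int(seen["year"].min()), int(seen["year"].max())
        x0, y0 = float(g["x"].iloc[0]), float(g["y"].iloc[0])
        byyear = {int(r.year): r for r in g.itertuples()}
        for yr in range(first_e, last_e + 1):
            r = byyear.get(yr)
            if r is not None and r.sprouted == 1:
                out_rows.append({
                    "id": ind, "year": yr, "alive": 1, "sprouted": 1,
                    "size": int(r.size), "flowering": int(r.flowering),
                    "flowers": int(r.flowers), "fruits": int(r.fruits),
                    "x": x0, "y": y0, "ambiguous": False,
                })
            else:
                out_rows.append({
                    "id": ind, "year": yr, "alive": 1, "sprouted": 0,
                    "size": 0, "flowering": 0, "flowers": 0, "fruits": 0,
                    "x": x0, "y": y0, "ambiguous": False,
                })
        gap = study_end - last_e
        if 1 <= gap <= k_ambiguous:
            out_rows[-1]["ambiguous"] = True
    return pd.DataFrame(out_rows)


def validate_life_history(table: pd.DataFrame, max_size: int | None = None) -> None:
    """Raise :class:`InvalidArgumentError` on any table-invariant violation."""
    t = table
    if (t["size"] < 0).any():
        raise InvalidArgumentError("negative size")
    if max_size is not None and (t["size"] > max_size).any():
        raise InvalidArgumentError("size above maximum")
    dormant = (t["alive"] == 1) & (t["sprouted"] == 0)
    if (t.loc[dormant, "size"] != 0).any() or (t.loc[dormant, "flowering"] != 0).any():
        raise InvalidArgumentError("dormant rows must have size 0 and no flowering")
    nonfl = t["flowering"] == 0
    if (t.loc[nonfl, "flowers"] != 0).any() or (t.loc[nonfl, "fruits"] != 0).any():
        raise InvalidArgumentError("flower/fruit counts must be 0 when not flowering")
    for ind, g in t.groupby("id"):
        yrs = np.sort(g["year"].to_numpy(int))
        if len(np.unique(yrs)) != len(yrs):
            raise InvalidArgumentError(f"duplicate years for individual {ind}")
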