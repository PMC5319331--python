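"""Conspecific density dependence: screening, the Ricker modifier and
plateau calibration.

Adaptive dynamics needs competition between genotypes, supplied here by
negative density dependence in a single vital rate.  Candidate rates are
screened by refitting each vital-rate GLM with local density (individuals
per 1 x 1 m grid cell) as an added fixed effect; the selected rate is then
multiplied by a Ricker factor

    rate * exp(alpha - beta * N)

with ``N`` the population density (established plants per m^2).  With
``alpha <= 0`` the factor never exceeds 1, so probabilities stay inside
[0, 1] without clipping, and a log-link scalar model reduces exactly to
the classic Ricker map ``N exp(alpha - beta N)``.  The multiplicative
form also keeps the modifier distinct from the evolving sprouting
intercept: an additive link-scale modifier on sprouting would be
collinear with the trait, and the density feedback would cancel the
trait out of the invasion gradient, leaving no interior ESS.  ``alpha``
and ``beta`` are calibrated so the density-coupled projection, started
from a single founder plant, reaches a stationary density matching the
plateau observed during monitoring.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .errors import (
    CalibrationError,
    EquilibriumError,
    InvalidArgumentError,
    MissingDataError,
    SelectionError,
)
from .matrix_builder import CompiledKernel, DemographicModel, dominant_eigen
from .synthetic_data import grid_density
from .vital_rates import FAMILIES, build_design, fit_vital_rate

#: documented priority order for selecting the density-dependent rate
DD_PRIORITY = ("sprouting", "survival", "flowering", "growth", "flowers")


@dataclass(frozen=True)
class RickerParams:
    """Multiplicative Ricker modifier for one vital rate.

    ``alpha`` is the modifier's intercept (dimensionless; must be <= 0 so
    the factor exp(alpha - beta N) cannot push a probability above 1);
    ``beta`` the per-capita crowding coefficient (per individuals m^-2);
    ``rate`` names the modified vital rate.  For a sprouting modifier,
    ``on_juveniles`` and ``on_adults`` select which emergence
    probabilities the factor multiplies (juvenile seedling emergence,
    adult sprouting, or both).  When adult sprouting is both the
    regulated rate and the evolving trait, the feedback suppresses the
    trait axis itself and no interior ESS can exist; population
    regulation through juvenile emergence (``on_adults=False``) keeps
    the trait axis free, matching the strong recruitment-stage density
    dependence typical of herbaceous perennials.
    """

    alpha: float
    beta: float
    rate: str = "sprouting"
    on_juveniles: bool = True
    on_adults: bool = True

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise InvalidArgumentError("beta must be >= 0 for negative density dependence")
        if self.alpha > 0:
            raise InvalidArgumentError("alpha must be <= 0 to keep probabilities in [0, 1]")


def apply_density_modifier(rate_value, N: float, params: RickerParams):
    """Modified rate ``x * exp(alpha - beta * N)`` (deterministic)."""
    return rate_value * np.exp(params.alpha - params.beta * float(N))


def local_density(table: pd.DataFrame, cell: float = 1.0) -> pd.DataFrame:
    """Per-individual local density covariate.

    Individuals (not sprouts) are counted on a grid of ``cell`` x ``cell``
    metres laid over the plot, per year; every individual inherits its
    cell's count.  Cell assignment uses the half-open rule [x, x + cell).
    """
    if not {"x", "y"}.issubset(table.columns):
        raise MissingDataError("table lacks x/y positions")
    out = table.copy()
    dens = np.zeros(len(out))
    for _, idx in out.groupby("year").indices.items():
        dens[idx] = grid_density(out["x"].to_numpy()[idx], out["y"].to_numpy()[idx], cell)
    out["density"] = dens
    return out


@dataclass
class DensityScreenResult:
    """Per-rate density slopes with a 2-standard-error sign classification."""

    table: pd.DataFrame  # columns: rate, slope, se, classification

    def classification(self, rate: str) -> str:
        row = self.table[self.table["rate"] == rate]
        if row.empty:
            raise InvalidArgumentError(f"rate {rate!r} not screened")
        return str(row["classification"].iloc[0])

    def negative_rates(self, priority=DD_PRIORITY) -> list[str]:
        neg = set(self.table.loc[self.table["classification"] == "negative", "rate"])
        ordered = [r for r in priority if r in neg]
        return ordered + sorted(neg - set(ordered))


def screen_density(
    table: pd.DataFrame,
    climate,
    design: str,
    responses=("survival", "sprouting", "growth", "flowering", "flowers"),
    base_terms: dict[str, tuple[str, ...]] | None = None,
    cell: float = 1.0,
) -> DensityScreenResult:
    """Refit each vital rate with density as an added fixed effect.

    Returns slope, standard error and a sign classification per rate:
    ``negative`` if slope + 2 SE < 0, ``positive`` if slope - 2 SE > 0,
    else ``none``.  Non-convergent refits are reported with
    classification ``nonconverged``.
    """
    if "density" not in table.columns:
        table = local_density(table, cell=cell)
    rows = []
    for resp in responses:
        base = ("siz_t", "flwyn_t") if base_terms is None else base_terms.get(resp, ("siz_t", "flwyn_t"))
        if resp == "flowers":
            base = tuple(t for t in base if t != "flwyn_t")
        terms = tuple(base) + ("density",)
        try:
            des = build_design(table, climate, design, resp)
            fit = fit_vital_rate(des, terms, FAMILIES[resp], name=resp)
        except Exception:
            rows.append({"rate": resp, "slope": np.nan, "se": np.nan,
                         "classification": "nonconverged"})
            continue
        if not fit.converged:
            rows.append({"rate": resp, "slope": np.nan, "se": np.nan,
                         "classification": "nonconverged"})
            continue
        slope = fit.spec.coef["density"]
        se = _density_se(des, fit)
        if slope + 2 * se < 0:
            cls = "negative"
        elif slope - 2 * se > 0:
            cls = "positive"
        else:
            cls = "none"
        rows.append({"rate": resp, "slope": slope, "se": se, "classification": cls})
    return DensityScreenResult(pd.DataFrame(rows))


def _density_se(design: pd.DataFrame, fit) -> float:
    """Wald standard error of the density slope from the observed
    information of the fitted GLM."""
    import statsmodels.api as sm

    from .vital_rates import _design_matrix

    X = _design_matrix(design, fit.spec.terms)
    y = design["y"].to_numpy(float)
    if fit.spec.response == "binomial":
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
    else:
        from statsmodels.discrete.truncated_model import TruncatedLFPoisson

        res = TruncatedLFPoisson(y, X, truncation=0).fit(disp=0, maxiter=200)
    i = 1 + list(fit.spec.terms).index("density")
    return float(np.sqrt(np.asarray(res.cov_params())[i, i]))


# ---------------------------------------------------------------------------
# density-coupled iteration
# ---------------------------------------------------------------------------

def iterate_to_equilibrium(
    kernel: CompiledKernel,
    d_spr: float = 0.0,
    founder: np.ndarray | None = None,
    rel_tol: float = 1e-6,
    window: int = 50,
    max_steps: int = 5000,
    polish: bool = True,
):
    """Iterate the density-coupled projection to its stationary density.

    Starts from a single plant in the first adult entry state and stops
    when the relative density change stays below ``rel_tol`` for
    ``window`` consecutive steps.  With ``polish=True`` the stationary
    density is then refined by root-finding on ``log lambda(A(N)) = 0``
    and the structure replaced by the dominant eigenvector, giving a
    machine-precision fixed point (required for exact invasion
    neutrality).

    Returns ``(structure, density)`` where ``structure`` is the
    stationary population vector scaled so its weighted density equals
    the stationary density.
    """
    model = kernel.model
    if model.dd is None:
        raise InvalidArgumentError("model has no calibrated density modifier")
    weights = kernel.space.density_weights
    area = model.plot_area
    n = np.zeros(kernel.n)
    if founder is None:
        n[kernel.space.founder_index] = 1.0
    else:
        n = np.asarray(founder, float).copy()
    dens = float((weights * n).sum() / area)
    collapse_floor = dens * 1e-8
    stable = 0
    for _ in range(max_steps):
        A = kernel.assemble(d_spr=d_spr, density=dens)
        n = A @ n
        new_dens = float((weights * n).sum() / area)
        if not np.isfinite(new_dens) or new_dens <= collapse_floor:
            raise EquilibriumError(
                "population collapsed or diverged during iteration"
            )
        rel = abs(new_dens - dens) / max(new_dens, 1e-300)
        dens = new_dens
        stable = stable + 1 if rel < rel_tol else 0
        if stable >= window:
            break
    else:
        # weak feedback relaxes slowly and is rescued by the root polish
        # below; without it the step budget is a hard failure
        if not polish:
            raise EquilibriumError("no stationary density within step budget")

    if polish:
        # lambda(A(N)) is strictly decreasing in N, so the stationary
        # density is the unique root of log lambda(N) = 0
        def loglam(N):
            return float(np.log(np.max(np.abs(
                np.linalg.eigvals(kernel.assemble(d_spr=d_spr, density=N))))))

        lo, hi = dens * 0.9, dens * 1.1
        flo, fhi = loglam(lo), loglam(hi)
        tries = 0
        while flo * fhi > 0 and tries < 60:
            if flo > 0 and fhi > 0:
                lo, hi = hi, hi * 2.0
            else:
                lo, hi = lo * 0.5, lo
            flo, fhi = loglam(lo), loglam(hi)
            tries += 1
        if flo * fhi <= 0:
            dens = brentq(loglam, lo, hi, xtol=1e-12, rtol=8.9e-16)
        _, w, _ = dominant_eigen(kernel.assemble(d_spr=d_spr, density=dens))
        denom = float((weights * w).sum())
        if denom <= 0:
            raise EquilibriumError("degenerate stationary structure")
        n = w * (dens * area / denom)
    return n, dens


def calibrate_ricker(
    model: DemographicModel,
    plateau_target: float,
    rate: str = "sprouting",
    alpha: float = 0.0,
    climate: dict[str, float] | None = None,
    on_juveniles: bool = True,
    on_adults: bool = True,
    rel_tol: float = 0.002,
) -> RickerParams:
    """Calibrate ``beta`` (with ``alpha`` profiled, default 0) so the
    density-coupled projection plateaus at ``plateau_target`` (established
    plants per m^2).

    The stationary density is monotone decreasing in ``beta``; the root is
    bracketed geometrically and solved by Brent's method to well inside
    the 2% contract.  Raises :class:`CalibrationError` when growth at zero
    density is insufficient (``lambda_0 <= 1``) or no ``beta`` in bounds
    yields the plateau.
    """
    if plateau_target <= 0:
        raise InvalidArgumentError("plateau_target must be > 0")
    kernel = model.with_dd(
        RickerParams(alpha, 0.0, rate, on_juveniles, on_adults)
    ).compile(climate)
    lam0 = float(np.max(np.abs(np.linalg.eigvals(kernel.assemble(density=0.0)))))
    if lam0 <= 1.0:
        raise CalibrationError(
            f"lambda at zero density is {lam0:.4f} <= 1; rate {rate!r} cannot "
            "produce asymptotic growth to a plateau"
        )

    def plateau(beta: float) -> float:
        k = model.with_dd(
            RickerParams(alpha, beta, rate, on_juveniles, on_adults)
        ).compile(climate)
        try:
            _, dens = iterate_to_equilibrium(k)
        except EquilibriumError as exc:
            raise CalibrationError(f"no stationary density at beta={beta:g}") from exc
        return dens

    # plateau(beta) is decreasing; bracket geometrically from the
    # scalar-Ricker guess N* ~ (log lambda0 + alpha) / beta
    beta = (np.log(lam0) + alpha) / plateau_target
    lo = hi = beta
    for _ in range(60):
        if plateau(lo) > plateau_target:
            break
        hi = lo
        lo /= 2.0
    else:
        raise CalibrationError("could not bracket plateau from below")
    for _ in range(60):
        if plateau(hi) < plateau_target:
            break
        lo = hi
        hi *= 2.0
    else:
        raise CalibrationError("could not bracket plateau from above")

    root = brentq(lambda b: plateau(b) - plateau_target, lo, hi,
                  xtol=1e-12, rtol=1e-6)
    params = RickerParams(alpha, float(root), rate, on_juveniles, on_adults)
    achieved = plateau(float(root))
    if abs(achieved - plateau_target) > rel_tol * plateau_target:
        raise CalibrationError(
            f"calibrated plateau {achieved:.4f} misses target {plateau_target:.4f}"
        )
    return params


def select_dd_rate(
    screen: DensityScreenResult,
    model: DemographicModel,
    plateau_target: float,
    priority=DD_PRIORITY,
) -> tuple[str, RickerParams]:
    """First negatively density-dependent rate (in priority order) for
    which Ricker calibration succeeds; mirrors the iterate-and-test
    procedure used to pick sprouting (historical design) or adult
    survival (age x stage design)."""
    failures = []
    for rate in screen.negative_rates(priority):
        if rate not in ("sprouting", "survival"):
            # the matrix kernel carries the modifier only for these rates
            failures.append((rate, "no modifier hook"))
            continue
        try:
            params = calibrate_ricker(model, plateau_target, rate=rate)
            return rate, params
        except CalibrationError as exc:
            failures.append((rate, str(exc)))
    raise SelectionError(f"no negatively density-dependent rate calibrated: {failures}")
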