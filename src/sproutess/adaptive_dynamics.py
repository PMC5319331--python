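"""Resident-invader simulation, pairwise invasibility and ESS location.

The evolving trait is the sprouting-model y-intercept deviation ``d_spr``:
an additive shift in the intrinsic tendency to sprout, regardless of plant
state or weather.  A resident with deviation ``d_res`` grows from a single
founder to its density-regulated plateau; a rare mutant with deviation
``d_mut`` is then introduced, distributed over states in proportion to the
resident's stationary structure, and its fitness measured as the mean
annual log growth of its share of the population.

Deterministic mode takes the strict rare-mutant limit: the environment
(density) is the resident's stationary density, held fixed, and the mean
log share growth is taken after an automatic burn-in, so it equals the log
dominant eigenvalue of the mutant matrix in the resident's environment to
numerical precision.  Stochastic mode couples resident and mutant through
the shared density and draws climate values and per-rate year deviations
each step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .density_dependence import iterate_to_equilibrium
from .errors import EquilibriumError, InvalidArgumentError, NoESSError
from .matrix_builder import CompiledKernel, DemographicModel

EXTINCT_FITNESS = -700.0  # log share below ~1e-300


@dataclass
class ResidentState:
    """A resident strategy at its density-regulated equilibrium."""

    d_res: float
    structure: np.ndarray
    density: float


def resident_equilibrium(
    model: DemographicModel,
    d_res: float,
    kernel: CompiledKernel | None = None,
) -> ResidentState:
    """Density-coupled iteration from a single founder to stationarity."""
    if kernel is None:
        kernel = model.compile()
    n, dens = iterate_to_equilibrium(kernel, d_spr=d_res)
    return ResidentState(d_res=d_res, structure=n, density=dens)


def invasion_fitness(
    model: DemographicModel,
    d_res: float,
    d_mut: float,
    steps: int = 100,
    mode: str = "deterministic",
    seed: int | None = None,
    kernel: CompiledKernel | None = None,
    resident: ResidentState | None = None,
) -> float:
    """Per-step log growth of a rare mutant's population share.

    ``steps`` annual time steps are averaged (after burn-in in
    deterministic mode).  A numerically extinct mutant returns a large
    negative fitness instead of -inf.
    """
    if steps < 1:
        raise InvalidArgumentError("steps must be >= 1")
    if kernel is None:
        kernel = model.compile()
    if resident is None:
        resident = resident_equilibrium(model, d_res, kernel)

    if mode == "deterministic":
        A = kernel.assemble(d_spr=d_mut, density=resident.density)
        m = resident.structure / resident.structure.sum()
        # burn-in: iterate until the per-step growth settles, then average
        prev = None
        for _ in range(2000):
            nxt = A @ m
            g = nxt.sum()
            if g <= 0:
                return EXTINCT_FITNESS
            m = nxt / g
            lg = np.log(g)
            if prev is not None and abs(lg - prev) < 1e-13:
                break
            prev = lg
        total = 0.0
        for _ in range(steps):
            nxt = A @ m
            g = nxt.sum()
            m = nxt / g
            total += np.log(g)
        return float(total / steps)

    if mode != "stochastic":
        raise InvalidArgumentError(f"unknown mode {mode!r}")

    rng = np.random.default_rng(seed)
    res_vec = resident.structure.copy()
    mut_vec = resident.structure / resident.structure.sum()  # one individual
    weights = kernel.space.density_weights
    area = model.plot_area
    share = mut_vec.sum() / (mut_vec.sum() + res_vec.sum())
    total = 0.0
    for _ in range(steps):
        # one drawn year, shared by both genotypes: climate values from the
        # configured marginals plus one year deviation per vital rate
        clim = {}
        for name, vs in model.climate_vars.items():
            v = rng.normal(vs.mean, vs.sd) if vs.sd > 0 else vs.mean
            if vs.kind == "nonneg":
                v = max(v, 0.0)
            elif vs.kind == "count":
                v = float(np.clip(np.round(v), 0, 366))
            clim[name] = float(v)
        devs = {name: (rng.normal(0.0, s.year_sd) if s.year_sd > 0 else 0.0)
                for name, s in model.specs.items()}
        dens = float((weights * (res_vec + mut_vec)).sum() / area)
        kern = model.compile(clim)
        A_res = kern.assemble(d_spr=d_res, density=dens, year_devs=devs)
        A_mut = kern.assemble(d_spr=d_mut, density=dens, year_devs=devs)
        res_vec = A_res @ res_vec
        mut_vec = A_mut @ mut_vec
        tot = mut_vec.sum() + res_vec.sum()
        new_share = mut_vec.sum() / tot if tot > 0 else 0.0
        if new_share < 1e-300:
            return EXTINCT_FITNESS
        total += np.log(new_share / share)
        share = new_share
    return float(total / steps)


@dataclass
class PIPGrid:
    """Invasion-fitness surface over resident x mutant trait values."""

    resident: np.ndarray
    mutant: np.ndarray
    fitness: np.ndarray  # shape (len(mutant), len(resident))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.fitness,
                            index=pd.Index(self.mutant, name="d_mut"),
                            columns=pd.Index(self.resident, name="d_res"))


def pip(
    model: DemographicModel,
    d_range: tuple[float, float] = (-3.0, 3.0),
    resolution: int = 21,
    mode: str = "deterministic",
    seed: int | None = None,
    mutant_values: np.ndarray | None = None,
) -> PIPGrid:
    """Pairwise invasibility grid.

    Rows are mutant deviations, columns resident deviations; each column
    shares one resident equilibrium.  The deviation range should span
    sprouting probabilities from roughly 0.2 to near-certain.
    """
    res_vals = np.linspace(d_range[0], d_range[1], resolution)
    mut_vals = res_vals if mutant_values is None else np.asarray(mutant_values, float)
    kernel = model.compile()
    F = np.empty((len(mut_vals), len(res_vals)))
    for j, dr in enumerate(res_vals):
        resident = resident_equilibrium(model, float(dr), kernel)
        for i, dm in enumerate(mut_vals):
            F[i, j] = invasion_fitness(model, float(dr), float(dm), mode=mode,
                                       seed=seed, kernel=kernel, resident=resident)
    return PIPGrid(res_vals, mut_vals, F)


def selection_gradient(
    model: DemographicModel,
    d: float,
    h: float = 1e-3,
    kernel: CompiledKernel | None = None,
    resident: ResidentState | None = None,
) -> float:
    """Central-difference derivative of invasion fitness with respect to
    the mutant trait, at the resident value."""
    if kernel is None:
        kernel = model.compile()
    if resident is None:
        resident = resident_equilibrium(model, d, kernel)
    up = invasion_fitness(model, d, d + h, kernel=kernel, resident=resident)
    dn = invasion_fitness(model, d, d - h, kernel=kernel, resident=resident)
    return (up - dn) / (2.0 * h)


@dataclass
class ESSEstimate:
    """Located optimum of the sprouting-intercept deviation."""

    d_star: float
    gradient: float
    convergence_stable: bool
    strategy_stable: bool
    se: float | None = None
    bootstrap_replicates: int = 0
    classification: str = field(init=False)

    def __post_init__(self) -> None:
        if self.convergence_stable and self.strategy_stable:
            self.classification = "stable (local ESS)"
        elif self.convergence_stable:
            self.classification = "convergence-stable branching point"
        else:
            self.classification = "unstable (repeller)"


def find_ess(
    model: DemographicModel,
    bounds: tuple[float, float] = (-3.0, 3.0),
    tol: float = 1e-6,
    h: float = 1e-3,
    coarse: int = 13,
    kernel: CompiledKernel | None = None,
) -> ESSEstimate:
    """Locate a singular strategy by root-finding on the selection
    gradient inside ``bounds``.

    A coarse scan brackets a sign change of the gradient; Brent's method
    refines it to ``|g| < tol`` (in trait units).  Classification checks
    convergence stability (gradient decreasing through zero) and strategy
    stability (fitness maximum in the mutant direction).  Raises
    :class:`NoESSError` when no bracketing is found.
    """
    if kernel is None:
        kernel = model.compile()

    cache: dict[float, float] = {}

    def g(d: float) -> float:
        d = float(d)
        if d not in cache:
            cache[d] = selection_gradient(model, d, h=h, kernel=kernel)
        return cache[d]

    def g_safe(d: float) -> float:
        # residents that cannot persist (lambda_0 <= 1) have no equilibrium
        try:
            return g(d)
        except EquilibriumError:
            return float("nan")

    xs = np.linspace(bounds[0], bounds[1], coarse)
    gs = [g_safe(float(x)) for x in xs]
    bracket = None
    for a, b, ga, gb in zip(xs[:-1], xs[1:], gs[:-1], gs[1:]):
        if np.isfinite(ga) and np.isfinite(gb) and np.sign(ga) != np.sign(gb):
            bracket = (float(a), float(b))
            break
    if bracket is None:
        raise NoESSError(f"selection gradient has no sign change in {bounds}")

    d_star = float(brentq(g, *bracket, xtol=tol))
    g_star = g(d_star)
    dh = max(10 * h, 1e-2)
    conv_stable = (g(d_star + dh) - g(d_star - dh)) < 0
    resident = resident_equilibrium(model, d_star, kernel)
    f0 = invasion_fitness(model, d_star, d_star, kernel=kernel, resident=resident)
    fp = invasion_fitness(model, d_star, d_star + dh, kernel=kernel, resident=resident)
    fm = invasion_fitness(model, d_star, d_star - dh, kernel=kernel, resident=resident)
    strat_stable = (fp - 2 * f0 + fm) < 0
    return ESSEstimate(d_star=d_star, gradient=g_star,
                       convergence_stable=bool(conv_stable),
                       strategy_stable=bool(strat_stable))


def bootstrap_ess(
    table: pd.DataFrame,
    pipeline,
    B: int = 100,
    seed: int = 0,
    bounds: tuple[float, float] = (-3.0, 3.0),
    max_failure_fraction: float = 0.2,
) -> tuple[float, list[float], bool]:
    """Hierarchical non-parametric bootstrap SE of the optimal deviation.

    Individuals are resampled with replacement (all records of an
    individual move together); ``pipeline(table) -> DemographicModel``
    refits the vital rates; :func:`find_ess` is re-run per replicate.
    Returns ``(se, estimates, reliable)``; replicate failures are logged
    and excluded, and more than ``max_failure_fraction`` of them marks the
    SE unreliable.
    """
    if B < 2:
        raise InvalidArgumentError("need at least 2 bootstrap replicates")
    rng = np.random.default_rng(seed)
    ids = table["id"].unique()
    groups = {i: g for i, g in table.groupby("id")}
    estimates: list[float] = []
    failures = 0
    for _ in range(B):
        chosen = rng.choice(ids, size=len(ids), replace=True)
        parts = []
        for new_id, old in enumerate(chosen):
            g = groups[old].copy()
            g["id"] = new_id
            parts.append(g)
        resampled = pd.concat(parts, ignore_index=True)
        try:
            model = pipeline(resampled)
            est = find_ess(model, bounds=bounds)
            estimates.append(est.d_star)
        except Exception:
            failures += 1
    if len(estimates) < 2:
        raise NoESSError("bootstrap produced fewer than 2 successful replicates")
    se = float(np.std(estimates, ddof=1))
    reliable = failures <= max_failure_fraction * B
    return se, estimates, reliable
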