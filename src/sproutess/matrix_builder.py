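"""Assemble annual projection matrices from vital-rate functions.

Every admissible transition arc is filled from the kernel decomposition

    a_D      = S * (1 - P)                 (survival without sprouting)
    a_k(V)   = S * P * g_k * (1 - F_k)     (growth to size k, vegetative)
    a_k(F)   = S * P * g_k * F_k           (growth to size k, flowering)

where ``S`` is survival from year t to t+1, ``P`` the conditional
sprouting probability in year t+1, ``g_k`` the truncated-Poisson growth
distribution over target sizes and ``F_k`` the flowering probability at
target size ``k``.  Fecundity arcs run from flowering states to the first
juvenile state under a pre-breeding census: seeds produced in year t enter
the seed/protocorm stage in year t+1.

For speed, a :class:`CompiledKernel` pre-computes every link-scale linear
predictor for a fixed climate; reassembling the matrix for a new trait
deviation, density or set of year deviations is then a vectorized O(n^2)
operation, which makes density-coupled equilibrium iteration and ESS
searches cheap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as _dc_replace
from typing import Any

import numpy as np
from scipy.special import expit, logit

from .errors import InvalidArgumentError, MissingCovariateError
from .life_cycle import StateSpace
from .synthetic_data import ClimateVarSpec
from .vital_rates import VitalRateSpec

__all__ = [
    "FecundityParams", "DemographicModel", "CompiledKernel",
    "ProjectionMatrix", "growth_distribution", "transition_entries",
    "build_annual_matrix", "dominant_lambda", "dominant_eigen",
    "perturb_fecundity",
]


@dataclass(frozen=True)
class FecundityParams:
    """Juvenile-recruitment parameters taken from the literature.

    These parametrize the unmonitored part of the life cycle: seed output
    per fruit, the fraction of seeds that germinate into a protocorm, and
    the protocorm-to-seedling transition probability.  ``fruit_set`` is
    the expected fruits per flower used when no fruiting models are
    fitted.  All three headline parameters are exercised by the +/-10%
    sensitivity harness (:func:`perturb_fecundity`).
    """

    seeds_per_fruit: float = 5000.0
    germination: float = 0.002
    protocorm_to_seedling: float = 0.5
    fruit_set: float = 0.2

    def __post_init__(self) -> None:
        for name in ("germination", "protocorm_to_seedling", "fruit_set"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidArgumentError(f"{name} must lie in [0, 1]")
        if self.seeds_per_fruit < 0:
            raise InvalidArgumentError("seeds_per_fruit must be >= 0")


def perturb_fecundity(params: FecundityParams, factor: float) -> FecundityParams:
    """Scale seeds per fruit, germination and protocorm transition by
    ``1 + factor`` (sensitivity harness; fractions above 1 are clipped
    with a warning)."""
    vals = {}
    for name in ("seeds_per_fruit", "germination", "protocorm_to_seedling"):
        v = getattr(params, name) * (1.0 + factor)
        if name != "seeds_per_fruit" and v > 1.0:
            warnings.warn(f"{name} clipped to 1.0 after perturbation")
            v = 1.0
        vals[name] = v
    return _dc_replace(params, **vals)


@dataclass
class DemographicModel:
    """Everything needed to build matrices: a state space, fitted (or
    declared) vital-rate specs, juvenile/fecundity configuration, climate
    marginals and the plot geometry."""

    space: StateSpace
    specs: dict[str, VitalRateSpec]
    fecundity: FecundityParams
    juveniles: dict[str, float]
    climate_vars: dict[str, ClimateVarSpec]
    plot_area: float = 400.0
    dd: Any = None  # RickerParams once calibrated

    def mean_climate(self) -> dict[str, float]:
        return {k: v.mean for k, v in self.climate_vars.items()}

    def juvenile_param(self, key) -> float:
        if isinstance(key, (int, float)):
            return float(key)
        table = dict(self.juveniles)
        table.setdefault("protocorm_to_seedling", self.fecundity.protocorm_to_seedling)
        if key not in table:
            raise InvalidArgumentError(f"juvenile parameter {key!r} not configured")
        return float(table[key])

    def with_dd(self, dd) -> "DemographicModel":
        return _dc_replace(self, dd=dd)

    def compile(self, climate: dict[str, float] | None = None) -> "CompiledKernel":
        return CompiledKernel(self, climate)


def truncated_poisson_pmf(mu: np.ndarray, kmax: int) -> np.ndarray:
    """Poisson pmf truncated and renormalized over {1..kmax}; shape
    (kmax, len(mu)); columns sum to 1."""
    if kmax < 1:
        raise InvalidArgumentError("max size must be >= 1")
    mu = np.atleast_1d(np.asarray(mu, float))
    if np.any(mu <= 0):
        raise InvalidArgumentError("Poisson mean must be > 0")
    ks = np.arange(1, kmax + 1, dtype=float)
    logpmf = ks[:, None] * np.log(mu)[None, :] - np.cumsum(np.log(ks))[:, None]
    logpmf -= logpmf.max(axis=0, keepdims=True)
    pmf = np.exp(logpmf)
    return pmf / pmf.sum(axis=0, keepdims=True)


def growth_distribution(size_spec: VitalRateSpec, cov: dict, max_size: int,
                        year_dev: float = 0.0) -> np.ndarray:
    """Growth distribution over target sizes 1..max (dormancy is handled
    by the sprouting probability, not here)."""
    if size_spec.response != "poisson":
        raise InvalidArgumentError("growth model must be Poisson/log")
    mu = np.exp(size_spec.linear_predictor(cov, year_dev=year_dev))
    return truncated_poisson_pmf(np.asarray([mu], float), max_size)[:, 0]


def transition_entries(S: float, P: float, g: np.ndarray, F: np.ndarray):
    """Kernel entries (a_D, a_V by size, a_F by size) for one source state."""
    g = np.asarray(g, float)
    F = np.broadcast_to(np.asarray(F, float), g.shape)
    a_d = S * (1.0 - P)
    a_v = S * P * g * (1.0 - F)
    a_f = S * P * g * F
    return a_d, a_v, a_f


@dataclass
class ProjectionMatrix:
    """A built annual matrix with its state index and build context.

    ``transition`` holds the survival-driven block and ``fecundity`` the
    reproduction arcs; ``A = transition + fecundity``.  ``survival`` is
    the per-source-column survival probability (the transition block's
    column sums equal it by construction).
    """

    A: np.ndarray
    transition: np.ndarray
    fecundity: np.ndarray
    survival: np.ndarray
    space: StateSpace
    context: dict = field(default_factory=dict)

    def validate(self, atol: float = 1e-10) -> None:
        if np.any(self.A < 0):
            raise InvalidArgumentError("negative matrix entry")
        colsums = self.transition.sum(axis=0)
        if np.max(np.abs(colsums - self.survival)) > atol:
            raise InvalidArgumentError("transition column sums do not match survival")


class CompiledKernel:
    """Link-scale pre-computation of all vital rates at a fixed climate.

    ``assemble`` produces the full matrix for a given sprouting-intercept
    deviation, population density and per-rate year deviations.  Density
    acts through the model's Ricker modifier (``alpha - beta * N`` on the
    link scale of the selected rate), the trait deviation through the
    adult sprouting intercept.
    """

    _ADULT_RATES = ("survival", "sprouting", "growth", "flowering")

    def __init__(self, model: DemographicModel, climate: dict[str, float] | None = None):
        self.model = model
        space = model.space
        self.space = space
        self.n = space.n
        self.climate = dict(model.mean_climate() if climate is None else climate)

        for rate in self._ADULT_RATES:
            if rate not in model.specs:
                raise InvalidArgumentError(f"missing vital-rate spec {rate!r}")
            if any(p == "density" for t in model.specs[rate].terms for p in t.split(":")):
                raise InvalidArgumentError(
                    "matrix specs must not carry a density term; use the Ricker modifier"
                )

        adult = np.flatnonzero(space.is_adult_column)
        self.adult_cols = adult
        nA = len(adult)
        m = space.max_size

        cov = self._adult_covariates(adult)
        self._cov = cov
        self.S_link = np.asarray(model.specs["survival"].linear_predictor(cov), float)
        self.P_link = np.asarray(model.specs["sprouting"].linear_predictor(cov), float)
        self.G_link = np.asarray(model.specs["growth"].linear_predictor(cov), float)

        fspec = model.specs["flowering"]
        f_base = np.full(nA, fspec.coef["intercept"], float)
        for t in fspec.terms:
            if t == "siz_next":
                continue
            if "siz_next" in t.split(":"):
                raise InvalidArgumentError("siz_next interactions are not supported")
            f_base = f_base + fspec.coef[t] * _term_value_arrays(t, cov)
        self.F_base = f_base
        self.F_siznext = float(fspec.coef.get("siz_next", 0.0))

        # per-column target indices
        self.dorm_target = np.empty(nA, int)
        self.TV = np.empty((m, nA), int)
        self.TF = np.empty((m, nA), int)
        for a, col in enumerate(adult):
            d, tv, tf = space.adult_targets(int(col))
            self.dorm_target[a] = d
            self.TV[:, a] = tv
            self.TF[:, a] = tf

        # fecundity: expected seed input per flowering source state
        self.flowering_cols = np.flatnonzero(space.is_flowering)
        self.flowers_link, self.fec_chain = self._fecundity_links(cov, adult)

        # juvenile columns: survival, emergence logit, resolved weights
        self._compile_juveniles()

        # growth/flowering weight cache for the zero-deviation case
        self._W0 = self._weights(0.0, 0.0)

    # -- compile helpers --------------------------------------------------
    def _adult_covariates(self, adult) -> dict[str, np.ndarray]:
        space = self.space
        siz_t = np.array([space.curr_stage[i].size for i in adult], float)
        flw_t = np.array([float(space.curr_stage[i].flowering) for i in adult])
        if space.kind == "historical":
            siz_p = np.array([space.prev_stage[i].size for i in adult], float)
            flw_p = np.array(
                [float(space.prev_stage[i].flowering and space.prev_stage[i].mature)
                 for i in adult]
            )
            age = np.zeros(len(adult))
        else:
            siz_p = np.zeros(len(adult))
            flw_p = np.zeros(len(adult))
            age = np.array([space.age[i] for i in adult], float)
        cov = {
            "siz_t": siz_t, "flwyn_t": flw_t,
            "siz_t1": siz_p, "flwyn_t1": flw_p,
            "grw_t": siz_t - siz_p, "age": age,
        }
        for k, v in self.climate.items():
            cov[k] = np.full(len(adult), float(v))
        return cov

    def _fecundity_links(self, cov, adult):
        model = self.model
        fl_cols = self.flowering_cols
        if len(fl_cols) == 0:
            return np.zeros(0), np.zeros(0)
        pos_in_adult = {int(c): a for a, c in enumerate(adult)}
        sub = {k: v[[pos_in_adult[int(c)] for c in fl_cols]] for k, v in cov.items()}
        if "flowers" in model.specs:
            fl_link = np.asarray(model.specs["flowers"].linear_predictor(sub), float)
        else:
            fl_link = np.zeros(len(fl_cols))  # one flower per flowering plant
        flowers = np.exp(fl_link)
        fec = model.fecundity
        if "fruiting" in model.specs and "fruits" in model.specs:
            sub = dict(sub)
            sub["flw_t"] = flowers
            p_fruit = expit(np.asarray(model.specs["fruiting"].linear_predictor(sub), float))
            n_fruit = np.exp(np.asarray(model.specs["fruits"].linear_predictor(sub), float))
            fruits_per_flowerer = p_fruit * n_fruit
            chain = fruits_per_flowerer / np.clip(flowers, 1e-12, None)
        else:
            chain = np.full(len(fl_cols), fec.fruit_set)
        chain = chain * fec.seeds_per_fruit * fec.germination
        return fl_link, chain

    def _compile_juveniles(self) -> None:
        model = self.model
        juv = []
        for jc in self.space.juvenile_columns:
            surv = model.juvenile_param(jc.surv_key)
            weights = np.array([model.juvenile_param(w) for w in jc.weights], float)
            if jc.sprout_key is not None:
                p = model.juvenile_param(jc.sprout_key)
                if not 0.0 < p < 1.0:
                    raise InvalidArgumentError("juvenile sprouting must lie in (0, 1)")
                if weights.size and abs(weights.sum() - 1.0) > 1e-8:
                    raise InvalidArgumentError(
                        f"conditional weights for column {jc.index} must sum to 1"
                    )
                juv.append((jc, surv, float(logit(p)), weights))
            else:
                juv.append((jc, surv, None, weights))
        self._juveniles = juv

    def _weights(self, growth_dev: float, flowering_dev: float) -> np.ndarray:
        """Conditional sprouted-target distribution per adult column
        (n x n, columns sum to 1 over the sprouted targets)."""
        m = self.space.max_size
        mu = np.exp(self.G_link + growth_dev)
        g = truncated_poisson_pmf(mu, m)
        ks = np.arange(1, m + 1, dtype=float)[:, None]
        F = expit(self.F_base[None, :] + self.F_siznext * ks + flowering_dev)
        W = np.zeros((self.n, self.n))
        cols = self.adult_cols[None, :]
        W[self.TV, cols] = g * (1.0 - F)
        W[self.TF, cols] = g * F
        return W

    # -- assembly ---------------------------------------------------------
    def _dd_factor(self, rate: str, density) -> float:
        """Multiplicative Ricker factor exp(alpha - beta N) for the
        selected rate (1.0 when density dependence does not apply)."""
        dd = self.model.dd
        if dd is None or density is None or dd.rate != rate:
            return 1.0
        return float(np.exp(dd.alpha - dd.beta * float(density)))

    def _juv_factor(self, density) -> float:
        dd = self.model.dd
        if dd is not None and density is not None and dd.rate == "sprouting" \
                and getattr(dd, "on_juveniles", True):
            return self._dd_factor("sprouting", density)
        return 1.0

    def survival_vector(self, density=None, year_devs=None) -> np.ndarray:
        """Per-column realized survival (the transition block's column
        sums equal this vector by construction)."""
        devs = year_devs or {}
        S = np.zeros(self.n)
        s_adult = expit(self.S_link + devs.get("survival", 0.0)) \
            * self._dd_factor("survival", density)
        S[self.adult_cols] = s_adult
        juv_fac = self._juv_factor(density)
        for jc, surv, sprout_logit, _ in self._juveniles:
            if sprout_logit is None:
                S[jc.index] = surv
            else:
                p = float(expit(sprout_logit + devs.get("sprouting", 0.0)))
                S[jc.index] = surv * (1.0 - p * (1.0 - juv_fac))
        return S

    def assemble(
        self,
        d_spr: float = 0.0,
        density: float | None = None,
        year_devs: dict[str, float] | None = None,
        parts: bool = False,
    ):
        devs = year_devs or {}
        dev_g = devs.get("growth", 0.0)
        dev_f = devs.get("flowering", 0.0)
        W = self._W0 if (dev_g == 0.0 and dev_f == 0.0) else self._weights(dev_g, dev_f)

        dd = self.model.dd
        S = expit(self.S_link + devs.get("survival", 0.0)) \
            * self._dd_factor("survival", density)
        P = expit(self.P_link + devs.get("sprouting", 0.0) + d_spr)
        if dd is None or getattr(dd, "on_adults", True):
            P = P * self._dd_factor("sprouting", density)

        T = np.zeros((self.n, self.n))
        T[:, self.adult_cols] = W[:, self.adult_cols] * (S * P)[None, :]
        np.add.at(T, (self.dorm_target, self.adult_cols), S * (1.0 - P))

        # Juvenile emergence: a crowding-suppressed seedling fails to
        # establish and dies (recruitment density dependence), so the
        # suppressed fraction of the emergence mass is mortality rather
        # than rerouted dormancy.
        juv_fac = self._juv_factor(density)
        for jc, surv, sprout_logit, weights in self._juveniles:
            if sprout_logit is None:
                T[list(jc.targets), jc.index] = surv * weights
            else:
                p = float(expit(sprout_logit + devs.get("sprouting", 0.0)))
                T[jc.dormant_target, jc.index] = surv * (1.0 - p)
                T[list(jc.targets), jc.index] = surv * p * juv_fac * weights

        Fec = np.zeros((self.n, self.n))
        if len(self.flowering_cols):
            entries = np.exp(self.flowers_link + devs.get("flowers", 0.0)) * self.fec_chain
            Fec[self.space.fecundity_target, self.flowering_cols] = entries

        if parts:
            return T + Fec, T, Fec
        return T + Fec

    def projection_matrix(self, d_spr=0.0, density=None, year_devs=None,
                          context=None) -> ProjectionMatrix:
        A, T, Fec = self.assemble(d_spr, density, year_devs, parts=True)
        return ProjectionMatrix(
            A=A, transition=T, fecundity=Fec,
            survival=self.survival_vector(density, year_devs),
            space=self.space,
            context={"climate": dict(self.climate), "d_spr": d_spr,
                     "density": density, **(context or {})},
        )


def _term_value_arrays(term: str, cov: dict) -> np.ndarray:
    try:
        out = 1.0
        for part in term.split(":"):
            out = out * cov[part]
        return np.asarray(out, float)
    except KeyError as exc:
        raise MissingCovariateError(str(exc))


def build_annual_matrix(
    model: DemographicModel,
    climate: dict[str, float] | None = None,
    d_spr: float = 0.0,
    density: float | None = None,
    mode: str = "deterministic",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> ProjectionMatrix:
    """Build one annual matrix.

    Deterministic mode uses the supplied (or mean) climate and zero year
    deviations.  Stochastic mode draws climate values from the model's
    configured marginal distributions and one year deviation per vital
    rate from its fitted between-year standard deviation.
    """
    if mode not in ("deterministic", "stochastic"):
        raise InvalidArgumentError(f"unknown mode {mode!r}")
    year_devs = None
    if mode == "stochastic":
        if rng is None:
            rng = np.random.default_rng(seed)
        drawn = {}
        for name, vs in model.climate_vars.items():
            v = rng.normal(vs.mean, vs.sd) if vs.sd > 0 else vs.mean
            if vs.kind == "nonneg":
                v = max(v, 0.0)
            elif vs.kind == "count":
                v = float(np.clip(np.round(v), 0, 366))
            drawn[name] = float(v)
        climate = drawn
        year_devs = {
            name: (rng.normal(0.0, s.year_sd) if s.year_sd > 0 else 0.0)
            for name, s in model.specs.items()
        }
    kernel = model.compile(climate)
    return kernel.projection_matrix(d_spr=d_spr, density=density, year_devs=year_devs,
                                    context={"mode": mode, "seed": seed})


def dominant_eigen(A: np.ndarray):
    """Dominant eigenvalue with right and left eigenvectors (all real,
    non-negative for a primitive non-negative matrix)."""
    if not np.all(np.isfinite(A)):
        raise InvalidArgumentError("non-finite matrix entries")
    vals, vecs = np.linalg.eig(A)
    i = int(np.argmax(np.abs(vals)))
    lam = float(np.abs(vals[i]))
    w = np.abs(np.real(vecs[:, i]))
    w = w / w.sum() if w.sum() > 0 else w
    vals_l, vecs_l = np.linalg.eig(A.T)
    j = int(np.argmax(np.abs(vals_l)))
    v = np.abs(np.real(vecs_l[:, j]))
    return lam, w, v


def dominant_lambda(A) -> float:
    """Spectral radius of a non-negative square matrix (deterministic
    population growth rate)."""
    M = A.A if isinstance(A, ProjectionMatrix) else np.asarray(A, float)
    if not np.all(np.isfinite(M)):
        raise InvalidArgumentError("non-finite matrix entries")
    return float(np.max(np.abs(np.linalg.eigvals(M))))


def export_matrix_market(pm: ProjectionMatrix, path_mtx, path_index=None) -> None:
    """MatrixMarket export with a sidecar CSV state index.

    The matrix is column-to-row oriented: entry (r, c) is the per-capita
    contribution of source state c to target state r.
    """
    from scipy.io import mmwrite
    from scipy.sparse import coo_matrix

    mmwrite(str(path_mtx), coo_matrix(pm.A),
            comment="column = source state; see state index CSV")
    if path_index is not None:
        pm.space.to_csv(path_index)


def import_matrix_market(path_mtx) -> np.ndarray:
    from scipy.io import mmread

    M = mmread(str(path_mtx))
    if hasattr(M, "todense"):
        M = M.todense()
    return np.asarray(M, float)
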