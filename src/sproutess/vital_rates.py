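"""Vital-rate regression models: declaration, fitting, selection, evaluation.

Each vital rate (survival, sprouting, growth, flowering, flower count and,
where configured, fruiting and fruit count) is a generalized linear model
on the individual-by-year transitions, with a binomial-logit or
Poisson-log response, main-effect and two-way-interaction terms drawn from
a global vocabulary, and a year-level intercept.

Covariate vocabulary (raw, unstandardized scales):

``siz_t``        size (sprout or leaf count) in year t
``flwyn_t``      flowered in year t (0/1)
``siz_t1``       size in year t-1 (historical design)
``flwyn_t1``     flowered in year t-1 (0/1)
``grw_t``        growth, siz_t - siz_t1 (signed)
``age``          years since first observation (age x stage design)
``dt32``         winter frost days for the transition year
``tpcp``         annual precipitation (mm) for the transition year
``sun``          April--May sunshine hours
``sprppt``       February--May precipitation (mm)
``density``      conspecific adults per square metre
``flw_t``        flower count in year t (fruiting models, replacing siz_t)
``siz_next``     target size in year t+1 (flowering models only)

Interactions are written ``"a:b"``.

The year effect is implemented as empirically shrunken year offsets: the
fixed-effects GLM is fitted first, then per-year intercept deviations are
estimated by a one-step weighted update and shrunk toward zero using a
method-of-moments estimate of the between-year variance.  This preserves
the year-deviation interface the stochastic matrices need without a full
mixed-model engine; a true GLMM backend can be plugged in by replacing
:func:`fit_vital_rate`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .errors import (
    EmptyDesignError,
    InvalidArgumentError,
    MissingCovariateError,
    SelectionError,
)

RESPONSES = (
    "survival",
    "sprouting",
    "growth",
    "flowering",
    "flowers",
    "fruiting",
    "fruits",
)

#: response family per vital rate
FAMILIES = {
    "survival": "binomial",
    "sprouting": "binomial",
    "growth": "poisson",
    "flowering": "binomial",
    "flowers": "poisson",
    "fruiting": "binomial",
    "fruits": "poisson",
}


def term_value(term: str, cov: dict) -> float:
    """Value of a (possibly interaction) term given a covariate mapping."""
    try:
        if ":" in term:
            out = 1.0
            for part in term.split(":"):
                out = out * cov[part]
            return out
        return cov[term]
    except KeyError as exc:  # pragma: no cover - message formatting
        raise MissingCovariateError(f"covariate {exc.args[0]!r} missing for term {term!r}")


@dataclass
class VitalRateSpec:
    """One declared or fitted vital-rate model.

    ``coef`` maps term names to coefficients and always contains
    ``"intercept"``.  ``year_effects`` maps year -> additive link-scale
    deviation; ``year_sd`` is the between-year standard deviation on the
    link scale.  ``d_spr`` slots into sprouting models as an additive
    intercept deviation (the evolving trait) and defaults to 0.
    """

    name: str
    response: str  # "binomial" | "poisson"
    terms: tuple[str, ...]
    coef: dict[str, float]
    year_effects: dict[int, float] = field(default_factory=dict)
    year_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.response not in ("binomial", "poisson"):
            raise InvalidArgumentError(f"unknown response {self.response!r}")
        missing = [t for t in self.terms if t not in self.coef]
        if missing or "intercept" not in self.coef:
            raise InvalidArgumentError(f"coefficients missing for {missing or ['intercept']}")
        if self.year_sd < 0:
            raise InvalidArgumentError("year_sd must be >= 0")

    @property
    def link(self) -> str:
        return "logit" if self.response == "binomial" else "log"

    def linear_predictor(self, cov: dict, year_dev: float = 0.0, d_spr: float = 0.0):
        """Link-scale value; works on scalars or aligned numpy arrays."""
        lp = self.coef["intercept"] + d_spr + year_dev
        for t in self.terms:
            lp = lp + self.coef[t] * term_value(t, cov)
        return lp

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "response": self.response,
            "terms": list(self.terms),
            "coef": dict(self.coef),
            "year_effects": {str(k): v for k, v in self.year_effects.items()},
            "year_sd": self.year_sd,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRateSpec":
        return cls(
            name=d["name"],
            response=d["response"],
            terms=tuple(d["terms"]),
            coef=dict(d["coef"]),
            year_effects={int(k): float(v) for k, v in d.get("year_effects", {}).items()},
            year_sd=float(d.get("year_sd", 0.0)),
        )


def eval_rate(spec: VitalRateSpec, cov: dict, year_dev: float = 0.0,
              d_spr: float = 0.0):
    """Invert the link on the linear predictor: a probability for binomial
    responses, a non-negative mean for Poisson responses."""
    lp = spec.linear_predictor(cov, year_dev=year_dev, d_spr=d_spr)
    return expit(lp) if spec.response == "binomial" else np.exp(lp)


@dataclass
class ModelFit:
    """A fitted candidate model with its small-sample AIC."""

    spec: VitalRateSpec
    loglik: float
    k: int            # fixed coefficients + 1 for the year-variance term
    n: int
    converged: bool = True

    @property
    def aicc(self) -> float:
        k, n = self.k, self.n
        if n <= k + 1:
            return float("inf")
        return -2.0 * self.loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

_CLIMATE_BY_DESIGN = {"historical": ("dt32", "tpcp"), "agestage": ("sun", "sprppt")}


def build_design(
    table: pd.DataFrame,
    climate,
    design: str,
    response: str,
    study_end: int | None = None,
    climate_lag: int = 0,
    climate_vars: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Assemble response rows and covariate columns for one vital rate.

    One row per valid individual-year transition.  Rows whose conditioning
    event fails (e.g. the individual did not survive, for the sprouting
    response) are excluded, as are rows flagged ambiguous by the dormancy
    censoring rule.  The historical design additionally requires a known
    year t-1 state.

    Climate covariates for a t -> t+1 transition are taken from the
    climate row of year ``t + 1 + climate_lag`` (same-year responses use
    year ``t + climate_lag``).
    """
    if response not in RESPONSES:
        raise InvalidArgumentError(f"unknown response {response!r}")
    if design not in ("historical", "agestage"):
        raise InvalidArgumentError(f"unknown design {design!r}")
    if climate_vars is None:
        climate_vars = _CLIMATE_BY_DESIGN[design]
    cdf = climate.data if hasattr(climate, "data") else climate

    df = table.sort_values(["id", "year"])
    if study_end is None:
        study_end = int(df["year"].max())
    has_density = "density" in df.columns

    rows: list[dict] = []
    for ind, g in df.groupby("id", sort=False):
        g = g.reset_index(drop=True)
        years = g["year"].to_numpy(int)
        byyear = {int(y): i for i, y in enumerate(years)}
        first_year = int(years.min())
        last_year = int(years.max())
        ambiguous_last = bool(g.get("ambiguous", pd.Series(False, index=g.index)).iloc[-1])
        for t in years:
            t = int(t)
            i_t = byyear[t]
            if design == "historical":
                if t - 1 not in byyear:
                    continue
                i_p = byyear[t - 1]
                hist = {
                    "siz_t1": float(g.loc[i_p, "size"]),
                    "flwyn_t1": float(g.loc[i_p, "flowering"]),
                }
            else:
                hist = {"age": float(t - first_year + 1)}
            base = {
                "id": ind,
                "year": t,
                "siz_t": float(g.loc[i_t, "size"]),
                "flwyn_t": float(g.loc[i_t, "flowering"]),
                **hist,
            }
            if design == "historical":
                base["grw_t"] = base["siz_t"] - base["siz_t1"]
            if has_density:
                base["density"] = float(g.loc[i_t, "density"])

            if response in ("survival", "sprouting", "growth", "flowering"):
                # forward-looking responses about year t+1
                survived = (t + 1) in byyear
                clim_year = t + 1 + climate_lag
                if clim_year not in cdf.index:
                    continue
                clim = {v: float(cdf.loc[clim_year, v]) for v in climate_vars if v in cdf.columns}
                if response == "survival":
                    if survived:
                        y = 1.0
                    elif t == last_year and not ambiguous_last and t < study_end:
                        y = 0.0
                    else:
                        continue
                    rows.append({**base, **clim, "y": y})
                    continue
                if not survived:
                    continue
                i_n = byyear[t + 1]
                sprouted = bool(g.loc[i_n, "sprouted"])
                if response == "sprouting":
                    rows.append({**base, **clim, "y": float(sprouted)})
                    continue
                if not sprouted:
                    continue
                if response == "growth":
                    rows.append({**base, **clim, "y": float(g.loc[i_n, "size"])})
                else:  # flowering
                    rows.append(
                        {**base, **clim, "siz_next": float(g.loc[i_n, "size"]),
                         "y": float(g.loc[i_n, "flowering"])}
                    )
            else:
                # same-year reproduction responses, conditional on flowering
                if not bool(g.loc[i_t, "flowering"]):
                    continue
                clim_year = t + climate_lag
                if clim_year not in cdf.index:
                    continue
                clim = {v: float(cdf.loc[clim_year, v]) for v in climate_vars if v in cdf.columns}
                flowers = float(g.loc[i_t, "flowers"])
                fruits = float(g.loc[i_t, "fruits"]) if "fruits" in g.columns else np.nan
                rec = {**base, **clim, "flw_t": flowers}
                if response == "flowers":
                    rec["y"] = flowers
                elif response == "fruiting":
                    if np.isnan(fruits):
                        continue
                    rec["y"] = float(fruits > 0)
                else:  # fruits
                    if np.isnan(fruits) or fruits <= 0:
                        continue
                    rec["y"] = fruits
                rows.append(rec)

    if not rows:
        raise EmptyDesignError(f"no usable rows for response {response!r}")
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, terms: tuple[str, ...]) -> np.ndarray:
    cols = [np.ones(len(df))]
    cov = {c: df[c].to_numpy(float) for c in df.columns if c not in ("y", "id")}
    for t in terms:
        cols.append(np.asarray(term_value(t, cov), dtype=float))
    return np.column_stack(cols)


def fit_vital_rate(
    design: pd.DataFrame,
    terms: tuple[str, ...] | list[str],
    family: str,
    name: str = "rate",
) -> ModelFit:
    """Maximum-likelihood GLM fit with shrunken year offsets.

    Returns a :class:`ModelFit`; separation or non-convergence is flagged
    (``converged=False``) rather than raised, so such fits can be excluded
    from model selection.
    """
    terms = tuple(terms)
    if len(design) < 1:
        raise EmptyDesignError("empty design")
    X = _design_matrix(design, terms)
    y = design["y"].to_numpy(float)
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            if family == "binomial":
                res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=200)
                converged = bool(getattr(res, "converged", True))
            else:
                # size, flower and fruit counts are conditional on the event
                # that produced them, hence zero-truncated
                from statsmodels.discrete.truncated_model import TruncatedLFPoisson

                res = TruncatedLFPoisson(y, X, truncation=0).fit(disp=0, maxiter=200)
                converged = bool(res.mle_retvals.get("converged", True))
            params = np.asarray(res.params, float)
            if not np.all(np.isfinite(params)) or np.max(np.abs(params)) > 1e3:
                converged = False
            elif family == "binomial" and np.min(np.abs(X @ params)) > 15:
                # fitted probabilities pinned to 0/1: (quasi-)separation
                converged = False
            loglik = float(res.llf)
        except Exception:
            converged = False
            params = np.zeros(X.shape[1])
            loglik = -np.inf

    coef = {"intercept": float(params[0])}
    coef.update({t: float(b) for t, b in zip(terms, params[1:])})
    spec = VitalRateSpec(name=name, response=family, terms=terms, coef=coef)

    if converged and "year" in design.columns:
        year_effects, year_sd = _shrunken_year_offsets(spec, design, X, y)
        spec = replace(spec, year_effects=year_effects, year_sd=year_sd)

    # k counts fixed coefficients plus one year-variance term
    k = len(terms) + 1 + 1
    return ModelFit(spec=spec, loglik=loglik, k=k, n=len(design), converged=converged)


def _shrunken_year_offsets(spec, design, X, y):
    """Per-year intercept deviations, shrunk by an empirical between-year
    variance (method of moments on one-step weighted updates)."""
    lp = X @ np.array([spec.coef["intercept"]] + [spec.coef[t] for t in spec.terms])
    if spec.response == "binomial":
        mu = expit(lp)
        w = np.clip(mu * (1 - mu), 1e-9, None)
    else:
        # zero-truncated Poisson mean and variance
        lam = np.exp(lp)
        mu = lam / np.clip(1.0 - np.exp(-lam), 1e-12, None)
        w = np.clip(mu * (1.0 + lam - mu), 1e-9, None)
    resid = y - mu
    years = design["year"].to_numpy(int)
    uniq = np.unique(years)
    raw = np.zeros(len(uniq))
    info = np.zeros(len(uniq))
    for i, yr in enumerate(uniq):
        m = years == yr
        info[i] = w[m].sum()
        raw[i] = resid[m].sum() / info[i]
    raw = raw - np.average(raw, weights=info)
    if len(uniq) > 1:
        var_raw = float(np.average(raw**2, weights=info))
        sampling = float(np.average(1.0 / info, weights=info))
        sigma2 = max(var_raw - sampling, 0.0)
    else:
        sigma2 = 0.0
    shrink = sigma2 / (sigma2 + 1.0 / info)
    devs = raw * shrink
    return {int(yr): float(d) for yr, d in zip(uniq, devs)}, float(np.sqrt(sigma2))


def enumerate_reduced_models(
    mains: list[str] | tuple[str, ...],
    interactions: list[str] | tuple[str, ...] = (),
) -> list[tuple[str, ...]]:
    """All reduced models from a global model, respecting marginality.

    An interaction ``"a:b"`` may appear only when both ``a`` and ``b`` are
    present.  Includes the intercept-only model (empty term tuple).
    """
    mains = list(mains)
    interactions = list(interactions)
    for ia in interactions:
        for part in ia.split(":"):
            if part not in mains:
                raise InvalidArgumentError(f"interaction {ia!r} references unknown main {part!r}")
    out: list[tuple[str, ...]] = []
    for r in range(len(mains) + 1):
        for main_sub in itertools.combinations(mains, r):
            ok_ints = [ia for ia in interactions if all(p in main_sub for p in ia.split(":"))]
            for ri in range(len(ok_ints) + 1):
                for int_sub in itertools.combinations(ok_ints, ri):
                    out.append(tuple(main_sub) + tuple(int_sub))
    return out


def select_model(fits: list[ModelFit], delta: float = 2.0) -> ModelFit:
    """Lowest-AICc fit, unless an equally parsimonious fit (delta-AICc
    within ``delta``) has strictly fewer parameters; ties broken by lower
    AICc then lexicographic term order."""
    converged = [f for f in fits if f.converged]
    if not converged:
        raise SelectionError("no converged candidate fits")
    best_aicc = min(f.aicc for f in converged)
    window = [f for f in converged if f.aicc - best_aicc <= delta]
    min_k = min(f.k for f in window)
    finalists = [f for f in window if f.k == min_k]
    finalists.sort(key=lambda f: (f.aicc, f.spec.terms))
    return finalists[0]


def selection_table(fits: list[ModelFit]) -> pd.DataFrame:
    """Candidate-model summary (terms, k, logLik, AICc, delta-AICc)."""
    rows = [
        {
            "terms": "+".join(f.spec.terms) or "(intercept)",
            "k": f.k,
            "loglik": f.loglik,
            "aicc": f.aicc,
            "converged": f.converged,
        }
        for f in fits
    ]
    out = pd.DataFrame(rows).sort_values("aicc").reset_index(drop=True)
    finite = out.loc[out["converged"], "aicc"]
    out["delta_aicc"] = out["aicc"] - (finite.min() if len(finite) else np.nan)
    return out
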