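"""Climate series management: observed vs simulated series, bias correction,
running-mean optimisation inputs and derived predictors.

A :class:`ClimateSeries` is a thin, validated wrapper around a pandas
DataFrame with one row per calendar year and one column per climate
variable.  Canonical variable names used throughout the package:

``temp``
    mean annual temperature (deg C)
``tpcp``
    total annual precipitation (mm)
``dt32``
    winter frost days -- number of days with minimum temperature at or
    below freezing (count, 0..366)
``sun``
    April--May sunshine hours
``sprppt``
    February--May precipitation (mm)
``rad_<m>``
    monthly mean surface shortwave radiation for month ``m`` (W m^-2)

Provenance is tracked per series as one of ``observed``, ``simulated`` or
``corrected``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import AlignmentError, InvalidArgumentError, NonConvergenceError

#: variables that cannot go negative and therefore use a ratio (or clipped
#: additive) bias correction / clipped predictions
NONNEGATIVE_VARIABLES = frozenset(
    {"tpcp", "sprppt", "dt32", "sun"} | {f"rad_{m}" for m in range(1, 13)}
)

COUNT_VARIABLES = frozenset({"dt32"})


@dataclass
class ClimateSeries:
    """Per-year climate variables with provenance.

    ``data`` is indexed by integer year (strictly increasing) with one
    float column per variable.
    """

    data: pd.DataFrame
    provenance: str = "observed"

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data).copy()
        df.index = df.index.astype(int)
        if not df.index.is_monotonic_increasing or df.index.has_duplicates:
            raise InvalidArgumentError("years must be strictly increasing")
        if "dt32" in df.columns:
            bad = (df["dt32"] < 0) | (df["dt32"] > 366)
            if bad.any():
                raise InvalidArgumentError("frost days must lie in [0, 366]")
        for col in df.columns:
            if col in NONNEGATIVE_VARIABLES and (df[col] < 0).any():
                raise InvalidArgumentError(f"{col} must be non-negative")
        self.data = df

    @property
    def years(self) -> np.ndarray:
        return self.data.index.to_numpy()

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def year_values(self, year: int) -> dict[str, float]:
        """Climate variables for one year as a plain dict."""
        if year not in self.data.index:
            raise KeyError(f"year {year} not in series")
        return {k: float(v) for k, v in self.data.loc[year].items()}

    def means(self) -> dict[str, float]:
        return {k: float(v) for k, v in self.data.mean().items()}

    def to_csv(self, path) -> None:
        out = self.data.copy()
        out.insert(0, "year", out.index)
        out["provenance"] = self.provenance
        out.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ClimateSeries":
        df = pd.read_csv(path)
        provenance = "observed"
        if "provenance" in df.columns:
            provenance = str(df["provenance"].iloc[0])
            df = df.drop(columns=["provenance"])
        df = df.set_index("year")
        return cls(df, provenance=provenance)

    def subset(self, years) -> "ClimateSeries":
        return replace(self, data=self.data.loc[list(years)])


def bias_correct(
    simulated: ClimateSeries,
    observed: ClimateSeries,
    precip_correction: str = "shift",
) -> ClimateSeries:
    """Shift a simulated series so its overlap-period means equal the
    observed means.

    Every shared variable is corrected by the additive difference in means
    over the overlapping years.  With ``precip_correction="ratio"`` the
    precipitation variables (``tpcp``, ``sprppt``) are instead scaled by
    the ratio of means, which preserves non-negativity.
    """
    overlap = simulated.data.index.intersection(observed.data.index)
    if len(overlap) == 0:
        raise AlignmentError("simulated and observed series share no years")
    shared = [v for v in simulated.variables if v in observed.variables]
    out = simulated.data.copy()
    for var in shared:
        obs_mean = float(observed.data.loc[overlap, var].mean())
        sim_mean = float(simulated.data.loc[overlap, var].mean())
        if precip_correction == "ratio" and var in {"tpcp", "sprppt"}:
            if sim_mean == 0:
                raise InvalidArgumentError(f"cannot ratio-correct {var}: zero mean")
            out[var] = out[var] * (obs_mean / sim_mean)
        else:
            out[var] = out[var] + (obs_mean - sim_mean)
    return ClimateSeries(out, provenance="corrected")


def running_mean_inputs(series: ClimateSeries, window_preceding: int = 25) -> pd.DataFrame:
    """Mean climate over each year and the ``window_preceding`` years before it.

    For year ``Y`` the output row is the mean over years ``Y - w .. Y``
    inclusive (``w + 1`` values).  Years without a complete window are
    omitted, not padded.  Missing interior years make the window incomplete.
    """
    if window_preceding < 0:
        raise InvalidArgumentError("window_preceding must be >= 0")
    w = int(window_preceding)
    df = series.data
    rows = {}
    yearset = set(int(y) for y in df.index)
    for year in df.index:
        window = range(int(year) - w, int(year) + 1)
        if all(y in yearset for y in window):
            rows[int(year)] = df.loc[list(window)].mean()
    out = pd.DataFrame(rows).T
    out.index.name = "year"
    return out


@dataclass
class DerivedPredictorModel:
    """Least-squares map from shared climate variables to a derived
    predictor (frost days or sunshine hours) with physical-bound clipping."""

    target: str
    predictors: list[str]
    coef: dict[str, float]  # includes "intercept"
    resid_std: float
    n: int
    lower: float = 0.0
    upper: float = float("inf")
    clip_warnings: int = field(default=0, compare=False)

    def predict(self, series: ClimateSeries) -> pd.Series:
        df = series.data
        missing = [p for p in self.predictors if p not in df.columns]
        if missing:
            raise InvalidArgumentError(f"series lacks predictors {missing}")
        yhat = np.full(len(df), self.coef["intercept"], dtype=float)
        for p in self.predictors:
            yhat = yhat + self.coef[p] * df[p].to_numpy(float)
        clipped = np.clip(yhat, self.lower, self.upper)
        self.clip_warnings += int(np.sum(clipped != yhat))
        return pd.Series(clipped, index=df.index, name=self.target)


def fit_derived_predictor(
    observed: ClimateSeries,
    target: str,
    predictors: list[str] | None = None,
) -> DerivedPredictorModel:
    """Fit a linear model for a derived predictor from variables shared
    between observed and simulated datasets (ordinary least squares)."""
    if predictors is None:
        predictors = [v for v in ("temp", "tpcp") if v in observed.variables]
    df = observed.data.dropna(subset=[target] + predictors)
    if len(df) < 10:
        raise InvalidArgumentError("need >= 10 complete years to fit a derived predictor")
    X = np.column_stack([np.ones(len(df))] + [df[p].to_numpy(float) for p in predictors])
    y = df[target].to_numpy(float)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise NonConvergenceError("rank-deficient predictor matrix")
    beta, res, _, _ = np.linalg.lstsq(X, y, rcond=None)
    fitted = X @ beta
    dof = max(len(df) - X.shape[1], 1)
    resid_std = float(np.sqrt(np.sum((y - fitted) ** 2) / dof))
    upper = 366.0 if target in COUNT_VARIABLES else float("inf")
    coef = {"intercept": float(beta[0])}
    coef.update({p: float(b) for p, b in zip(predictors, beta[1:])})
    return DerivedPredictorModel(
        target=target, predictors=list(predictors), coef=coef,
        resid_std=resid_std, n=len(df), lower=0.0, upper=upper,
    )


@dataclass(frozen=True)
class SuehrckeConstants:
    """Site constants for converting monthly shortwave radiation to
    sunshine duration.

    The relation maps the monthly clearness index (radiation relative to
    the extraterrestrial monthly mean) to a relative sunshine duration,
    which is multiplied by astronomical day length.  All constants are
    site configuration, supplied from the literature, not code.
    """

    #: extraterrestrial monthly mean irradiance per month (W m^-2)
    extraterrestrial: dict[int, float]
    #: mean day length per month (hours)
    day_length: dict[int, float]
    #: clear-sky clearness index (dimensionless)
    clear_sky_index: float = 0.7
    #: days per month used for the monthly total
    days_in_month: dict[int, int] = field(
        default_factory=lambda: {4: 30, 5: 31}
    )


def southern_england_constants() -> SuehrckeConstants:
    """Literature-style default constants for a mid-latitude (~51 N) site."""
    return SuehrckeConstants(
        extraterrestrial={4: 352.0, 5: 417.0},
        day_length={4: 13.8, 5: 15.5},
        clear_sky_index=0.7,
    )


def sunshine_from_radiation(
    monthly_radiation: dict[int, float],
    constants: SuehrckeConstants | None = None,
    months: tuple[int, ...] = (4, 5),
) -> float:
    """Estimate April--May sunshine hours from monthly shortwave radiation.

    The monthly clearness index ``K = H / H0`` is mapped to relative
    sunshine duration ``f = (K / K_clear)^2`` (monotone in radiation),
    clipped to [0, 1]; hours are ``f x day_length x days`` summed over the
    requested months.  Radiation above the clear-sky bound is clipped with
    a warning count returned via the function attribute ``last_clipped``.
    """
    if constants is None:
        constants = southern_england_constants()
    clipped = 0
    hours = 0.0
    for m in months:
        H = float(monthly_radiation[m])
        if H < 0:
            raise InvalidArgumentError("radiation must be >= 0")
        H0 = constants.extraterrestrial[m]
        K = H / H0
        f = (K / constants.clear_sky_index) ** 2
        if f > 1.0:
            f = 1.0
            clipped += 1
        hours += f * constants.day_length[m] * constants.days_in_month.get(m, 30)
    sunshine_from_radiation.last_clipped = clipped
    return hours


sunshine_from_radiation.last_clipped = 0
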