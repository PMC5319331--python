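"""Vital-rate models: evaluation, fitting, AICc selection, enumeration."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit, logit

from sproutess.errors import (
    EmptyDesignError,
    InvalidArgumentError,
    MissingCovariateError,
    SelectionError,
)
from sproutess.vital_rates import (
    FAMILIES,
    ModelFit,
    VitalRateSpec,
    build_design,
    enumerate_reduced_models,
    eval_rate,
    fit_vital_rate,
    select_model,
)


def make_spec(coef, response="binomial", name="rate", year_sd=0.0):
    terms = tuple(k for k in coef if k != "intercept")
    return VitalRateSpec(name=name, response=response, terms=terms,
                         coef=dict(coef), year_sd=year_sd)


class TestEvalRate:
    def test_all_zero_coefficients_gives_half(self):
        spec = make_spec({"intercept": 0.0, "siz_t": 0.0})
        assert eval_rate(spec, {"siz_t": 3.0}) == pytest.approx(0.5)

    def test_parviflorum_sprouting_intercept(self):
        # intercept-only evaluation of the fitted sprouting y-intercept
        spec = make_spec({"intercept": -2.065})
        assert eval_rate(spec, {}) == pytest.approx(expit(-2.065), abs=1e-12)
        assert eval_rate(spec, {}) == pytest.approx(0.1126, abs=5e-4)

    def test_sprouting_deviation_adds_on_link_scale(self):
        # y-intercept 0.237 plus optimal deviation 0.844
        spec = make_spec({"intercept": 0.237})
        out = eval_rate(spec, {}, d_spr=0.844)
        assert out == pytest.approx(expit(1.081), abs=1e-12)
        assert out == pytest.approx(0.7467, abs=5e-4)

    def test_interaction_terms_multiply(self):
        spec = make_spec({"intercept": 0.0, "siz_t": 0.0, "grw_t": 0.0,
                          "siz_t:grw_t": 0.5})
        cov = {"siz_t": 2.0, "grw_t": 3.0}
        assert eval_rate(spec, cov) == pytest.approx(expit(3.0))

    def test_poisson_response_is_nonnegative_mean(self):
        spec = make_spec({"intercept": 1.0, "siz_t": 0.2}, response="poisson")
        assert eval_rate(spec, {"siz_t": 2.0}) == pytest.approx(np.exp(1.4))

    def test_missing_covariate_raises(self):
        spec = make_spec({"intercept": 0.0, "siz_t": 1.0})
        with pytest.raises(MissingCovariateError):
            eval_rate(spec, {})

    def test_monotone_in_positive_coefficient_covariate(self):
        spec = make_spec({"intercept": -1.0, "siz_t": 0.7})
        vals = [eval_rate(spec, {"siz_t": s}) for s in range(6)]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSpecSerialization:
    def test_json_round_trip(self):
        import json

        spec = make_spec({"intercept": -2.065, "siz_t": 0.3, "siz_t:flwyn_t": -0.1,
                          "flwyn_t": 0.0}, year_sd=0.4)
        spec.year_effects = {2000: 0.12, 2001: -0.05}
        back = VitalRateSpec.from_dict(json.loads(json.dumps(spec.to_dict())))
        assert back == spec


class TestFitVitalRate:
    def test_balanced_intercept_is_zero(self):
        df = pd.DataFrame({"y": [1.0] * 50 + [0.0] * 50, "year": 2000})
        fit = fit_vital_rate(df, (), "binomial")
        assert fit.spec.coef["intercept"] == pytest.approx(0.0, abs=1e-6)

    def test_eighty_twenty_intercept_is_logit(self):
        df = pd.DataFrame({"y": [1.0] * 80 + [0.0] * 20, "year": 2000})
        fit = fit_vital_rate(df, (), "binomial")
        assert fit.spec.coef["intercept"] == pytest.approx(logit(0.8), abs=1e-6)
        assert fit.spec.coef["intercept"] == pytest.approx(1.3863, abs=1e-4)

    def test_slope_recovery_within_3_se(self, rng):
        n = 10000
        siz = rng.integers(0, 8, n).astype(float)
        p = expit(-0.5 + 0.5 * siz)
        y = (rng.random(n) < p).astype(float)
        df = pd.DataFrame({"y": y, "siz_t": siz, "year": 2000})
        fit = fit_vital_rate(df, ("siz_t",), "binomial")
        # Fisher-information SE of the slope
        import statsmodels.api as sm

        X = np.column_stack([np.ones(n), siz])
        cov = sm.GLM(y, X, family=sm.families.Binomial()).fit().cov_params()
        se = float(np.sqrt(cov[1, 1]))
        assert fit.spec.coef["siz_t"] == pytest.approx(0.5, abs=3 * se)

    def test_zero_truncated_poisson_recovery(self, rng):
        n = 6000
        x = rng.normal(0, 1, n)
        lam = np.exp(0.6 + 0.3 * x)
        y = np.array([np.random.default_rng(i).poisson(l) for i, l in enumerate(lam)])
        keep = y >= 1
        df = pd.DataFrame({"y": y[keep].astype(float), "siz_t": x[keep], "year": 2000})
        fit = fit_vital_rate(df, ("siz_t",), "poisson")
        assert fit.spec.coef["siz_t"] == pytest.approx(0.3, abs=0.05)

    def test_separation_flagged_not_raised(self):
        df = pd.DataFrame({"y": [0.0] * 20 + [1.0] * 20,
                           "siz_t": [0.0] * 20 + [1.0] * 20, "year": 2000})
        fit = fit_vital_rate(df, ("siz_t",), "binomial")
        assert not fit.converged

    def test_year_offsets_shrink_toward_zero(self, rng):
        years = np.repeat(np.arange(2000, 2010), 200)
        devs = {y: d for y, d in zip(range(2000, 2010), rng.normal(0, 0.8, 10))}
        p = expit(0.3 + np.array([devs[y] for y in years]))
        df = pd.DataFrame({"y": (rng.random(len(years)) < p).astype(float),
                           "year": years})
        fit = fit_vital_rate(df, (), "binomial")
        assert fit.spec.year_sd > 0.2
        est = np.array([fit.spec.year_effects[y] for y in range(2000, 2010)])
        true = np.array([devs[y] for y in range(2000, 2010)])
        assert np.corrcoef(est, true - true.mean())[0, 1] > 0.7

    def test_empty_design_raises(self):
        with pytest.raises(EmptyDesignError):
            fit_vital_rate(pd.DataFrame({"y": []}), (), "binomial")


class TestAICc:
    @given(st.floats(-500, -1), st.integers(2, 10), st.integers(30, 500))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_aicc_identity(self, loglik, k, n):
        spec = make_spec({"intercept": 0.0})
        fit = ModelFit(spec=spec, loglik=loglik, k=k, n=n)
        expected = -2 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert fit.aicc == pytest.approx(expected)


def _fit_with_aicc(aicc, k, n=1000, terms=()):
    # invert the AICc identity to produce a fit with the requested value
    loglik = -(aicc - 2 * k - 2 * k * (k + 1) / (n - k - 1)) / 2
    spec = make_spec({"intercept": 0.0, **{t: 0.0 for t in terms}})
    return ModelFit(spec=spec, loglik=loglik, k=k, n=n)


class TestSelectModel:
    def test_fewer_parameters_wins_inside_delta_window(self):
        a = _fit_with_aicc(100.0, k=5, terms=("siz_t", "flwyn_t", "grw_t"))
        b = _fit_with_aicc(101.5, k=3, terms=("siz_t",))
        assert select_model([a, b]) is b

    def test_outside_delta_window_best_aicc_wins(self):
        a = _fit_with_aicc(100.0, k=5, terms=("siz_t", "flwyn_t", "grw_t"))
        b = _fit_with_aicc(102.5, k=3, terms=("siz_t",))
        assert select_model([a, b]) is a

    def test_single_candidate_returned(self):
        a = _fit_with_aicc(50.0, k=2)
        assert select_model([a]) is a

    def test_never_worse_than_best_plus_delta(self, rng):
        fits = [_fit_with_aicc(100 + rng.uniform(0, 10), k=int(k), terms=tuple(f"t{i}" for i in range(int(k) - 2)))
                for k in rng.integers(2, 8, 12)]
        best = min(f.aicc for f in fits)
        assert select_model(fits).aicc <= best + 2.0

    def test_all_nonconverged_raises(self):
        a = _fit_with_aicc(100.0, k=2)
        a.converged = False
        with pytest.raises(SelectionError):
            select_model([a])


class TestEnumerateReducedModels:
    def test_two_mains_one_interaction_gives_five(self):
        models = enumerate_reduced_models(["a", "b"], ["a:b"])
        expected = {(), ("a",), ("b",), ("a", "b"), ("a", "b", "a:b")}
        assert set(models) == expected

    def test_single_main_gives_two(self):
        assert set(enumerate_reduced_models(["a"])) == {(), ("a",)}

    @given(st.integers(1, 4), st.integers(0, 3))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_marginality_respected(self, n_mains, n_ints):
        mains = [f"m{i}" for i in range(n_mains)]
        pairs = [(a, b) for i, a in enumerate(mains) for b in mains[i + 1:]]
        ints = [f"{a}:{b}" for a, b in pairs[:n_ints]]
        for model in enumerate_reduced_models(mains, ints):
            for term in model:
                if ":" in term:
                    assert all(p in model for p in term.split(":"))

    def test_unknown_interaction_component_raises(self):
        with pytest.raises(InvalidArgumentError):
            enumerate_reduced_models(["a"], ["a:b"])


def toy_table(rows):
    return pd.DataFrame(rows, columns=["id", "year", "alive", "sprouted", "size",
                                       "flowering", "flowers", "fruits", "x", "y"])


def toy_climate(years):
    from sproutess.climate_forecast import ClimateSeries

    return ClimateSeries(pd.DataFrame({"dt32": [100.0] * len(years),
                                       "tpcp": [1000.0] * len(years)},
                                      index=list(years)))


class TestBuildDesign:
    def test_three_consecutive_years_give_one_historical_survival_row(self):
        table = toy_table([
            (1, 2000, 1, 1, 2, 0, 0, 0, 1.0, 1.0),
            (1, 2001, 1, 1, 3, 0, 0, 0, 1.0, 1.0),
            (1, 2002, 1, 1, 3, 0, 0, 0, 1.0, 1.0),
        ])
        des = build_design(table, toy_climate(range(1999, 2005)), "historical",
                           "survival", study_end=2002)
        # only year 2001 has both a known t-1 state and a t+1 outcome
        assert len(des) == 1
        assert des.iloc[0]["year"] == 2001
        assert des.iloc[0]["grw_t"] == 1.0

    def test_sprouting_rows_condition_on_survival(self):
        table = toy_table([
            (1, 2000, 1, 1, 2, 0, 0, 0, 1.0, 1.0),
            (1, 2001, 1, 1, 2, 0, 0, 0, 1.0, 1.0),   # dies after 2001
            (2, 2000, 1, 1, 1, 0, 0, 0, 2.0, 2.0),
            (2, 2001, 1, 1, 1, 0, 0, 0, 2.0, 2.0),
            (2, 2002, 1, 0, 0, 0, 0, 0, 2.0, 2.0),
        ])
        des = build_design(table, toy_climate(range(1999, 2005)), "historical",
                           "sprouting", study_end=2002)
        # individual 1's death year contributes no sprouting row
        assert set(des["id"]) == {2}
        assert des.iloc[0]["y"] == 0.0  # dormant in 2002

    def test_hand_enumerated_survival_rows_with_one_death(self):
        # 10 individuals observed 2000-2003; individual 0 dies after 2001
        rows = []
        for ind in range(10):
            last = 2001 if ind == 0 else 2003
            for year in range(2000, last + 1):
                rows.append((ind, year, 1, 1, 2, 0, 0, 0, float(ind), 0.0))
        table = toy_table(rows)
        des = build_design(table, toy_climate(range(1999, 2006)), "historical",
                           "survival", study_end=2003)
        # per individual: years with known t-1 state and scorable outcome are
        # 2001, 2002 (2003 is censored by study end); individual 0 only 2001
        assert len(des) == 9 * 2 + 1
        assert des.loc[des["id"] == 0, "y"].tolist() == [0.0]

    def test_agestage_age_covariate(self):
        table = toy_table([
            (1, 2000, 1, 1, 2, 0, 0, 0, 1.0, 1.0),
            (1, 2001, 1, 1, 2, 0, 0, 0, 1.0, 1.0),
            (1, 2002, 1, 1, 2, 0, 0, 0, 1.0, 1.0),
        ])
        from sproutess.climate_forecast import ClimateSeries

        clim = ClimateSeries(pd.DataFrame({"sun": [200.0] * 6, "sprppt": [350.0] * 6},
                                          index=list(range(1999, 2005))))
        des = build_design(table, clim, "agestage", "survival", study_end=2002)
        assert des["age"].tolist() == [1.0, 2.0]

    def test_unknown_response_raises(self):
        with pytest.raises(InvalidArgumentError):
            build_design(toy_table([]), toy_climate(range(3)), "historical", "nope")


class TestTermRecovery:
    def test_selection_recovers_generating_terms(self):
        """Exhaustive AICc selection finds the true model structure in most
        replicates when the generating effect is strong."""
        hits = 0
        reps = 8
        for rep in range(reps):
            rng = np.random.default_rng(1000 + rep)
            n = 4000
            siz = rng.integers(0, 6, n).astype(float)
            flw = rng.integers(0, 2, n).astype(float)
            p = expit(-0.5 + 0.45 * siz)  # flwyn_t truly absent
            df = pd.DataFrame({"y": (rng.random(n) < p).astype(float),
                               "siz_t": siz, "flwyn_t": flw,
                               "year": rng.integers(2000, 2010, n)})
            fits = [fit_vital_rate(df, terms, "binomial")
                    for terms in enumerate_reduced_models(["siz_t", "flwyn_t"],
                                                          ["siz_t:flwyn_t"])]
            if select_model(fits).spec.terms == ("siz_t",):
                hits += 1
        assert hits >= 0.8 * reps
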