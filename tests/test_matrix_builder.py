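"""Matrix assembly: kernel entries, conservation, eigenvalues, fecundity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit
from scipy.stats import poisson

from sproutess.errors import InvalidArgumentError
from sproutess.matrix_builder import (
    FecundityParams,
    build_annual_matrix,
    dominant_lambda,
    growth_distribution,
    perturb_fecundity,
    transition_entries,
    truncated_poisson_pmf,
)
from sproutess.vital_rates import VitalRateSpec, eval_rate


class TestGrowthDistribution:
    def test_matches_direct_pmf_computation(self):
        spec = VitalRateSpec("growth", "poisson", (), {"intercept": float(np.log(2.0))})
        g = growth_distribution(spec, {}, max_size=9)
        raw = poisson.pmf(np.arange(1, 10), 2.0)
        assert np.allclose(g, raw / raw.sum(), atol=1e-12)
        assert g.sum() == pytest.approx(1.0, abs=1e-12)

    def test_small_mean_concentrates_on_one(self):
        spec = VitalRateSpec("growth", "poisson", (), {"intercept": -8.0})
        g = growth_distribution(spec, {}, max_size=9)
        assert g[0] > 0.999

    @given(st.floats(0.05, 8.0), st.integers(1, 12))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_always_normalized(self, mu, kmax):
        g = truncated_poisson_pmf(np.array([mu]), kmax)[:, 0]
        assert g.sum() == pytest.approx(1.0, abs=1e-12)
        assert (g >= 0).all()

    def test_invalid_max_size(self):
        with pytest.raises(InvalidArgumentError):
            truncated_poisson_pmf(np.array([1.0]), 0)


class TestTransitionEntries:
    def test_dormancy_entry(self):
        a_d, _, _ = transition_entries(0.9, 0.8, np.array([1.0]), np.array([0.0]))
        assert a_d == pytest.approx(0.18)

    def test_vegetative_and_flowering_entries(self):
        _, a_v, a_f = transition_entries(0.9, 0.8, np.array([0.5]), np.array([0.25]))
        assert a_v[0] == pytest.approx(0.27)
        assert a_f[0] == pytest.approx(0.09)

    @given(st.floats(0, 1), st.floats(0, 1), st.floats(0, 1),
           st.lists(st.floats(0.01, 1), min_size=2, max_size=9))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_survival_conservation_identity(self, S, P, F, weights):
        g = np.array(weights)
        g = g / g.sum()
        a_d, a_v, a_f = transition_entries(S, P, g, F)
        assert a_d + a_v.sum() + a_f.sum() == pytest.approx(S, abs=1e-12)


class TestBuildAnnualMatrix:
    def test_deterministic_is_reproducible(self, parv):
        a = build_annual_matrix(parv.model)
        b = build_annual_matrix(parv.model)
        assert np.array_equal(a.A, b.A)

    def test_column_matches_scalar_evaluation(self, parv):
        """One adult column of the vectorized kernel equals the entries
        hand-assembled from eval_rate and the kernel equations."""
        model = parv.model
        space = model.space
        pm = build_annual_matrix(model)
        col = space.adult_pair_index("V2", "V3")
        prev, curr = space.prev_stage[col], space.curr_stage[col]
        cov = {"siz_t": float(curr.size), "flwyn_t": float(curr.flowering),
               "siz_t1": float(prev.size), "flwyn_t1": float(prev.flowering),
               "grw_t": float(curr.size - prev.size), "age": 0.0,
               **model.mean_climate()}
        S = eval_rate(model.specs["survival"], cov)
        P = eval_rate(model.specs["sprouting"], cov)
        g = growth_distribution(model.specs["growth"], cov, space.max_size)
        fl = model.specs["flowering"]
        F = np.array([expit(fl.coef["intercept"] + fl.coef["siz_next"] * k)
                      for k in range(1, space.max_size + 1)])
        a_d, a_v, a_f = transition_entries(S, P, g, F)
        d_t, tv, tf = space.adult_targets(col)
        assert pm.A[d_t, col] == pytest.approx(a_d, abs=1e-12)
        assert np.allclose(pm.A[tv, col], a_v, atol=1e-12)
        assert np.allclose(pm.A[tf, col], a_f, atol=1e-12)

    def test_full_space_orders(self):
        from sproutess.life_cycle import cypripedium_state_space, ophrys_state_space

        assert cypripedium_state_space().n == 395
        assert ophrys_state_space().n == 173

    def test_stochastic_mode_seeded(self, parv):
        a = build_annual_matrix(parv.model, mode="stochastic", seed=11)
        b = build_annual_matrix(parv.model, mode="stochastic", seed=11)
        c = build_annual_matrix(parv.model, mode="stochastic", seed=12)
        assert np.array_equal(a.A, b.A)
        assert not np.array_equal(a.A, c.A)

    def test_stochastic_mean_converges_to_deterministic(self, oph):
        """With small between-year variance the entrywise mean of
        stochastic matrices approaches the deterministic matrix."""
        from dataclasses import replace as dc_replace

        from sproutess.synthetic_data import ClimateVarSpec

        model = oph.model
        small = {
            k: ClimateVarSpec(v.mean, v.sd * 0.05, v.kind)
            for k, v in model.climate_vars.items()
        }
        specs = {k: dc_replace(s, year_sd=s.year_sd * 0.05)
                 for k, s in model.specs.items()}
        m = dc_replace(model, climate_vars=small, specs=specs)
        det = build_annual_matrix(m).A
        rng = np.random.default_rng(4)
        draws = np.stack([build_annual_matrix(m, mode="stochastic", rng=rng).A
                          for _ in range(1200)])
        mean = draws.mean(axis=0)
        se = draws.std(axis=0, ddof=1) / np.sqrt(draws.shape[0])
        # allowance of order sigma^2 for the Jensen bias of the inverse links
        assert np.all(np.abs(mean - det) <= 3 * se + 1e-9 + 2e-3 * det)

    def test_structural_zeros_respect_admissible_arcs(self, parv):
        from sproutess.life_cycle import admissible_arcs

        pm = build_annual_matrix(parv.model)
        allowed = {(r, c) for r, c, _ in admissible_arcs(parv.model.space)}
        nz = np.argwhere(pm.A > 0)
        for r, c in nz:
            assert (int(r), int(c)) in allowed

    def test_survival_conservation_random_builds(self, parv, oph, rng):
        """Transition-block column sums equal the survival probabilities to
        1e-12 across randomly parameterized builds."""
        for i in range(30):
            ana = parv if i % 2 == 0 else oph
            model = ana.model
            kernel = model.compile({k: rng.normal(v.mean, max(v.sd, 1e-6))
                                    for k, v in model.climate_vars.items()})
            devs = {k: rng.normal(0, 0.3) for k in model.specs}
            d_spr = rng.normal(0, 1)
            A, T, Fec = kernel.assemble(d_spr=d_spr, year_devs=devs, parts=True)
            S = kernel.survival_vector(year_devs=devs)
            assert np.max(np.abs(T.sum(axis=0) - S)) < 1e-12


class TestDominantLambda:
    def test_identity_matrix(self):
        assert dominant_lambda(np.eye(7)) == pytest.approx(1.0)

    def test_two_by_two_characteristic_polynomial(self):
        A = np.array([[0.0, 2.0], [0.5, 0.0]])
        assert dominant_lambda(A) == pytest.approx(1.0, abs=1e-12)

    def test_matches_power_iteration_oracle(self, rng):
        A = rng.uniform(0, 1, (50, 50))
        v = np.ones(50)
        for _ in range(10000):
            w = A @ v
            lam = w.sum() / v.sum()
            v = w / np.linalg.norm(w)
        assert dominant_lambda(A) == pytest.approx(lam, abs=1e-6)

    def test_nonfinite_entries_raise(self):
        with pytest.raises(InvalidArgumentError):
            dominant_lambda(np.array([[np.nan, 0.0], [0.0, 1.0]]))


class TestPerturbFecundity:
    def test_plus_ten_percent(self):
        p = FecundityParams(germination=0.5)
        assert perturb_fecundity(p, 0.10).germination == pytest.approx(0.55)

    def test_down_then_up_is_not_identity(self):
        p = FecundityParams(seeds_per_fruit=1000.0)
        out = perturb_fecundity(perturb_fecundity(p, -0.10), 0.10)
        assert out.seeds_per_fruit == pytest.approx(990.0)

    def test_fraction_clipped_with_warning(self):
        p = FecundityParams(germination=0.95)
        with pytest.warns(UserWarning):
            out = perturb_fecundity(p, 0.10)
        assert out.germination == 1.0

    def test_ess_robust_to_juvenile_parameter_uncertainty(self, parv, parv_model):
        """The located optimum moves little under +/-10% juvenile-parameter
        perturbation (sensitivity harness)."""
        from dataclasses import replace as dc_replace

        from sproutess.adaptive_dynamics import find_ess
        from sproutess.density_dependence import calibrate_ricker

        base = find_ess(parv_model, bounds=(-2, 2)).d_star
        for factor in (-0.10, 0.10):
            fec = perturb_fecundity(parv.model.fecundity, factor)
            model = dc_replace(parv.model, fecundity=fec)
            params = calibrate_ricker(model, parv.plateau_target,
                                      rate=parv.dd_rate, on_adults=parv.dd_on_adults)
            shifted = find_ess(model.with_dd(params), bounds=(-2, 2)).d_star
            assert abs(shifted - base) < 0.1
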