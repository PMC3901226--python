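"""Error functions, viability verdicts, Monte Carlo bound, initial point."""

import numpy as np
import pytest

from kinens.decomposition import choose_independent_fluxes
from kinens.exceptions import FeasibilityError
from kinens.flux_regression import pI_to_flat
from kinens.preprocessing import interior_profiles, smooth_dataset
from kinens.viability import (Bounds, FluxErrorObjective, OptimizerConfig,
                              check_viable, confidence_bound_from_minima,
                              estimate_error_bound, find_initial_point, phi_C,
                              phi_R, phi_S)
from kinens.fixtures import branched_fixture
from tests.conftest import exact_profiles


@pytest.fixture(scope="module")
def branched_exact():
    fx = branched_fixture(noise_cv=0.0)
    dec = choose_independent_fluxes(fx.model)
    prof = exact_profiles(fx.model, fx.noise_free, fx.times)
    ptrue = {j: fx.truth[j] for j in dec.independent_indices}
    return fx, dec, prof, ptrue


class TestPhiR:
    def test_zero_at_truth_on_exact_data(self, branched_exact):
        fx, dec, prof, ptrue = branched_exact
        assert phi_R(pI_to_flat(dec, ptrue), dec, prof) < 1e-10

    def test_doubled_prediction_gives_one(self):
        """Mean squared relative error of pred = 2*target is exactly 1."""
        target = np.array([1.0, 2.0, 0.5, 3.0])
        pred = 2.0 * target
        rel = ((pred - target) / np.maximum(np.abs(target), 1e-8)) ** 2
        assert np.mean(rel) == pytest.approx(1.0)

    def test_invariant_to_common_flux_rescaling(self, branched_exact):
        """Scaling all gammas (hence all fluxes and slopes) by c leaves the
        relative flux error unchanged."""
        fx, dec, prof, ptrue = branched_exact
        c = 3.0
        scaled_model = fx.model.with_parameters(
            type(fx.truth)({j: (c * p[0],) + p[1:]
                            for j, p in fx.truth.values.items()}))
        dec_c = choose_independent_fluxes(scaled_model)
        prof_c = exact_profiles(scaled_model, fx.noise_free, fx.times)
        p_c = {j: (c * fx.truth[j][0],) + fx.truth[j][1:]
               for j in dec_c.independent_indices}
        phi_base = phi_R(pI_to_flat(dec, ptrue), dec, prof)
        phi_scaled = phi_R(pI_to_flat(dec_c, p_c), dec_c, prof_c)
        assert phi_scaled == pytest.approx(phi_base, abs=1e-12)

    def test_nonviable_candidate_gives_infinity(self, branched_exact):
        fx, dec, prof, _ = branched_exact
        bad = {j: fx.truth[j] for j in dec.independent_indices}
        bad[5] = (90.0, fx.truth[5][1])
        assert phi_R(pI_to_flat(dec, bad), dec, prof) == np.inf


class TestPhiSPhiC:
    def test_near_zero_at_truth(self, branched_exact):
        fx, dec, prof, ptrue = branched_exact
        assert phi_S(fx.truth, fx.model, prof) < 1e-12
        assert phi_C(fx.truth, fx.model, fx.data, fx.initial_state,
                     rtol=1e-9, atol=1e-11) < 1e-9

    def test_doubled_concentrations_give_one(self, branched_exact):
        fx, _, _, _ = branched_exact
        pred = 2.0 * fx.data.concentrations
        rel = ((pred - fx.data.concentrations) /
               np.maximum(np.abs(fx.data.concentrations), 1e-8)) ** 2
        assert np.mean(rel) == pytest.approx(1.0)

    def test_phi_s_decreases_with_noise(self):
        """Slope error at the true parameters shrinks as data noise shrinks."""
        vals = []
        for cv in (0.10, 0.01, 0.001):
            fx = branched_fixture(noise_cv=cv, seed=123)
            prof = interior_profiles(smooth_dataset(fx.data))
            vals.append(phi_S(fx.truth, fx.model, prof))
        assert vals[0] > vals[1] > vals[2]

    def test_simulation_failure_gives_infinite_phi_c(self):
        """A finite-time blow-up (autocatalytic x' = x^2) is reported as an
        infinite concentration error, not an exception."""
        from kinens.model_core import KineticModel, PowerLawFlux
        from kinens.preprocessing import TimeSeriesData

        model = KineticModel(np.array([[1.0]]),
                             [PowerLawFlux(1.0, {0: 2.0})], ["X1"])
        t = np.linspace(0, 5, 20)  # diverges before t = 1 from x0 = 1
        data = TimeSeriesData(t, np.ones((20, 1)), ["X1"])
        assert phi_C(None, model, data, np.array([1.0])) == np.inf


class TestCheckViable:
    def test_all_constraints_pass_at_truth(self, branched_exact):
        fx, dec, prof, ptrue = branched_exact
        bounds = Bounds.from_model(fx.model)
        res = check_viable(pI_to_flat(dec, ptrue), dec, prof, bounds, 1e-3)
        assert res.viable and res.violations == []

    def test_param_bound_violation_detected(self, branched_exact):
        fx, dec, prof, ptrue = branched_exact
        bounds = Bounds.from_model(fx.model)
        bad = dict(ptrue)
        bad[0] = (150.0, ptrue[0][1])  # gamma1 above its upper bound 100
        res = check_viable(bad, dec, prof, bounds, 1e-3)
        assert not res.viable
        assert res.violations[0]["kind"] == "param_bound"

    def test_positivity_violation_detected(self, branched_exact):
        fx, dec, prof, ptrue = branched_exact
        bounds = Bounds.from_model(fx.model)
        bad = dict(ptrue)
        bad[5] = (90.0, ptrue[5][1])
        res = check_viable(bad, dec, prof, bounds, 1e-3)
        assert not res.viable
        assert res.violations[0]["kind"] == "positivity"

    def test_phi_bound_monotonicity(self, branched_exact):
        """Viable at bound b implies viable at any larger bound."""
        fx, dec, prof, ptrue = branched_exact
        bounds = Bounds.from_model(fx.model)
        p = pI_to_flat(dec, ptrue)
        verdicts = [check_viable(p, dec, prof, bounds, b).viable
                    for b in (1e-12, 1e-6, 1e-3, 1.0)]
        assert verdicts == sorted(verdicts)


class TestOrderStatisticBound:
    def test_fifth_largest_of_hundred(self):
        assert confidence_bound_from_minima(np.arange(1, 101), 0.95) == 96.0

    def test_n20_returns_largest(self):
        values = np.arange(20, 0, -1)
        assert confidence_bound_from_minima(values, 0.95) == 20.0

    def test_identical_minima_return_that_value(self):
        assert confidence_bound_from_minima(np.full(30, 0.2), 0.95) == 0.2


class TestFindInitialPoint:
    def test_beats_truth_on_noise_free_data(self, branched_exact):
        fx, dec, prof, ptrue = branched_exact
        bounds = Bounds.from_model(fx.model)
        p0, phi0 = find_initial_point(dec, prof, bounds, seed=1,
                                      optimizer_config=OptimizerConfig(n_starts=6))
        assert phi0 <= phi_R(pI_to_flat(dec, ptrue), dec, prof) + 1e-6

    def test_matches_grid_on_1d_problem(self):
        """With all but one independent parameter pinned near truth, the
        optimizer matches a dense 1-D grid minimum."""
        fx = branched_fixture(noise_cv=0.02, seed=6)
        dec = choose_independent_fluxes(fx.model)
        prof = interior_profiles(smooth_dataset(fx.data))
        obj = FluxErrorObjective(dec, prof, Bounds.from_model(fx.model))
        base = pI_to_flat(dec, {j: fx.truth[j] for j in dec.independent_indices})

        def phi_of_g1(g):
            p = base.copy()
            p[0] = g
            return obj.phi(p)

        grid = np.linspace(0.5, 5.0, 451)
        vals = [phi_of_g1(g) for g in grid]
        g_star = grid[int(np.argmin(vals))]
        from scipy.optimize import minimize_scalar
        res = minimize_scalar(phi_of_g1, bounds=(0.5, 5.0), method="bounded")
        assert abs(res.x - g_star) <= grid[1] - grid[0]

    def test_infeasible_bounds_raise(self, branched_exact):
        fx, dec, prof, _ = branched_exact
        lo = {j: np.full(fx.model.fluxes[j].n_params, 99.0)
              for j in range(fx.model.n_fluxes)}
        hi = {j: np.full(fx.model.fluxes[j].n_params, 100.0)
              for j in range(fx.model.n_fluxes)}
        bounds = Bounds(lo, hi, flux_upper=5e5)
        with pytest.raises(FeasibilityError):
            find_initial_point(dec, prof, bounds, seed=0,
                               optimizer_config=OptimizerConfig(n_starts=2,
                                                                maxiter=100))


class TestErrorBound:
    def test_reproducible_under_fixed_seed(self):
        fx = branched_fixture(noise_cv=0.10, seed=3)
        dec = choose_independent_fluxes(fx.model)
        bounds = Bounds.from_model(fx.model)
        kw = dict(n_mc=10, seed=7, mode="reevaluate",
                  optimizer_config=OptimizerConfig(n_starts=1, maxiter=150))
        b1 = estimate_error_bound(fx.data, dec, bounds, **kw)
        b2 = estimate_error_bound(fx.data, dec, bounds, **kw)
        assert b1 == b2

    def test_zero_noise_gives_degenerate_replicates(self):
        """On noise-free data the smoothing residual variance is ~0, so all
        perturbed replicates coincide with the data and the bound collapses
        to the (noise-free) re-evaluated error value."""
        fx = branched_fixture(noise_cv=0.0)
        dec = choose_independent_fluxes(fx.model)
        bounds = Bounds.from_model(fx.model)
        bound = estimate_error_bound(
            fx.data, dec, bounds, n_mc=5, seed=1, mode="reevaluate",
            optimizer_config=OptimizerConfig(n_starts=4, maxiter=400))
        assert bound < 1e-2

    def test_bound_spread_shrinks_with_more_replicates(self):
        """The across-seed spread of the bound shrinks from n_mc=20 to 100
        (order statistics stabilize with more replicates); checked on a tiny
        random chain so many bounds stay cheap."""
        from kinens.fixtures import random_gma_fixture

        fx = random_gma_fixture(2, 3, seed=11, noise_cv=0.10,
                                time_grid=np.linspace(0, 5, 21))
        dec = choose_independent_fluxes(fx.model)
        bounds = Bounds.from_model(fx.model)

        def bounds_for(n_mc, seeds):
            return [estimate_error_bound(
                fx.data, dec, bounds, n_mc=n_mc, seed=s, mode="reevaluate",
                optimizer_config=OptimizerConfig(n_starts=1, maxiter=120))
                for s in seeds]

        seeds = (1, 2, 3, 4, 5, 6)
        small = bounds_for(20, seeds)
        large = bounds_for(100, seeds)
        assert np.std(np.log(large)) < np.std(np.log(small))
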