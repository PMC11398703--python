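"""Equilibrium solver, KKT verification, potential function, stability."""

import numpy as np
import pytest

from distgame import (
    GroupSpec,
    NoInteriorEquilibriumError,
    blend_risk_factors,
    cost,
    check_stability,
    potential,
    potential_risk,
    schedule_to_strategy,
    solve_equilibrium,
    solve_multigroup,
    verify_equilibrium,
)
from distgame.catalog import ActivityCatalog, logistic_inverse
from conftest import random_simplex


class TestSolveEquilibrium:
    def test_contact_factor_round_trip(self, casa, complete_schedule):
        """Solving with w = contact factors recovers the schedule that
        defined them: 14 h/week on activity 1 down to 1 h/week on 17-20."""
        eq = solve_equilibrium(casa.risk_profile(1.0), casa)
        np.testing.assert_allclose(
            eq.x_star, schedule_to_strategy(complete_schedule), atol=2e-5
        )
        hours = np.round(eq.hours())
        np.testing.assert_array_equal(hours, complete_schedule.hours)

    def test_impact_factor_round_trip(self, casa, free_schedule):
        eq = solve_equilibrium(casa.risk_profile(0.0), casa)
        np.testing.assert_allclose(
            eq.x_star, schedule_to_strategy(free_schedule), atol=2e-5
        )
        assert round(eq.hours()[15]) == 20  # workplaces

    def test_equal_factors_give_uniform(self, casa):
        prof = blend_risk_factors(np.full(20, 2.4), np.full(20, 2.4), 0.7)
        eq = solve_equilibrium(prof, casa)
        np.testing.assert_allclose(eq.x_star, 1 / 20, atol=1e-12)

    @pytest.mark.parametrize("delta", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_residual_across_severities(self, casa, delta):
        eq = solve_equilibrium(casa.risk_profile(delta), casa)
        assert eq.residual <= 1e-10
        assert eq.x_star.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(eq.x_star > 0)

    def test_agrees_with_bisection_oracle(self, casa):
        """Brent root-finding agrees with plain bisection on the
        normalization g(lambda) = sum_i sigma^-1(lambda/w_i) - 1."""
        prof = casa.risk_profile(0.5)
        w, kap, th = prof.w, casa.kappa, casa.theta

        def g(lam):
            return np.sum(logistic_inverse(lam / w, kap, th)) - 1.0

        lo, hi = 1e-12, float(np.min(w)) * 0.999
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if g(mid) < 0:
                lo = mid
            else:
                hi = mid
        eq = solve_equilibrium(prof, casa)
        assert eq.lambda_star == pytest.approx(0.5 * (lo + hi), abs=1e-10)

    def test_no_interior_equilibrium_detected(self, casa):
        """Wildly unequal factors push a coordinate to the boundary."""
        w = np.r_[np.full(19, 1.0), 2000.0]
        prof = blend_risk_factors(w, w, 1.0)
        with pytest.raises(NoInteriorEquilibriumError):
            solve_equilibrium(prof, casa)


class TestVerifyEquilibrium:
    def test_solver_output_verifies(self, casa):
        prof = casa.risk_profile(0.25)
        eq = solve_equilibrium(prof, casa)
        report = verify_equilibrium(eq.x_star, prof, casa)
        assert report
        assert report.lambda_ == pytest.approx(eq.lambda_star, abs=1e-10)

    def test_uniform_with_unequal_factors_fails(self, casa):
        report = verify_equilibrium(np.full(20, 0.05), casa.risk_profile(1.0), casa)
        assert not report
        assert report.max_complementarity > 1e-4

    def test_perturbed_equilibrium_fails(self, casa):
        prof = casa.risk_profile(0.5)
        eq = solve_equilibrium(prof, casa)
        x = eq.x_star.copy()
        x[0] += 0.05
        x /= x.sum()
        assert not verify_equilibrium(x, prof, casa)


class TestPotential:
    def test_gradient_matches_activity_risks(self, casa, rng):
        """Finite differences of the potential recover p_i(y)."""
        prof = casa.risk_profile(0.5)
        y = random_simplex(rng, 20)
        h = 1e-7
        grad = np.empty(20)
        for i in range(20):
            yp, ym = y.copy(), y.copy()
            yp[i] += h
            ym[i] -= h
            grad[i] = (potential(yp, prof, casa) - potential(ym, prof, casa)) / (2 * h)
        np.testing.assert_allclose(grad, potential_risk(y, prof, casa), atol=1e-6)

    def test_equilibrium_minimizes_potential_locally(self, casa, rng):
        prof = casa.risk_profile(0.5)
        eq = solve_equilibrium(prof, casa)
        f_star = potential(eq.x_star, prof, casa)
        for _ in range(1000):
            d = rng.normal(size=20) * 0.01
            d -= d.mean()  # stay on the simplex tangent
            y = eq.x_star + d
            if np.any(y < 0):
                continue
            y /= y.sum()
            assert potential(y, prof, casa) > f_star

    def test_grid_search_oracle_three_activities(self):
        """Dense simplex grid search at n=3 finds the potential minimum at
        the closed-form equilibrium, within grid resolution."""
        cat = ActivityCatalog(["a", "b", "c"], [1.0, 1.5, 2.3], [1.0, 1.5, 2.3])
        prof = cat.risk_profile(1.0)
        eq = solve_equilibrium(prof, cat)
        step = 1e-3
        g1 = np.arange(0.0, 1.0 + step / 2, step)
        x1, x2 = np.meshgrid(g1, g1, indexing="ij")
        keep = x1 + x2 <= 1.0 + 1e-12
        x1, x2 = x1[keep], x2[keep]
        grid = np.column_stack([x1, x2, 1.0 - x1 - x2])
        z = cat.kappa * (grid - cat.theta)
        f = (prof.w / cat.kappa * np.logaddexp(0.0, z)).sum(axis=1)
        best = grid[np.argmin(f)]
        np.testing.assert_allclose(best, eq.x_star, atol=2 * step)


class TestStability:
    @pytest.mark.parametrize("delta", [0.0, 0.5, 1.0])
    def test_interior_equilibria_are_stable(self, casa, delta):
        prof = casa.risk_profile(delta)
        eq = solve_equilibrium(prof, casa)
        assert check_stability(eq, prof, casa)

    def test_invasion_inequality(self, casa, rng):
        """x* resists invasion: against the slightly invaded population the
        incumbent strategy stays strictly cheaper than the invader."""
        prof = casa.risk_profile(0.5)
        eq = solve_equilibrium(prof, casa)
        eps = 0.01
        for _ in range(200):
            y = random_simplex(rng, 20)
            z = eps * y + (1 - eps) * eq.x_star
            assert cost(eq.x_star, z, prof, casa) < cost(y, z, prof, casa)


class TestMultigroup:
    def test_single_group_matches_plain_solver(self, casa):
        spec = GroupSpec(delta=[0.5], fractions=[1.0])
        mg = solve_multigroup(spec, casa)
        eq = solve_equilibrium(casa.risk_profile(0.5), casa)
        np.testing.assert_allclose(mg.groups[0].x_star, eq.x_star, atol=1e-12)
        np.testing.assert_allclose(mg.population, eq.x_star, atol=1e-12)

    def test_four_group_endpoints_recover_schedules(
        self, casa, complete_schedule, free_schedule
    ):
        """The delta=1 group equilibrates on the complete-distancing
        schedule, the delta=0 group on the free schedule."""
        spec = GroupSpec(delta=[0.0, 0.25, 0.75, 1.0], fractions=[0.25] * 4)
        mg = solve_multigroup(spec, casa)
        np.testing.assert_allclose(
            mg.groups[3].x_star, schedule_to_strategy(complete_schedule), atol=2e-5
        )
        np.testing.assert_allclose(
            mg.groups[0].x_star, schedule_to_strategy(free_schedule), atol=2e-5
        )
        assert mg.eq3_residual < 1e-7

    @pytest.mark.parametrize("s", [0.5, 1.0, 2.0])
    def test_equilibria_independent_of_coupling(self, casa, s):
        spec = GroupSpec(delta=[0.0, 1.0], fractions=[0.5, 0.5], s=s)
        ref = GroupSpec(delta=[0.0, 1.0], fractions=[0.5, 0.5], s=1.0)
        mg, mg_ref = solve_multigroup(spec, casa), solve_multigroup(ref, casa)
        for a, b in zip(mg.groups, mg_ref.groups):
            np.testing.assert_allclose(a.x_star, b.x_star, atol=1e-14)

    def test_population_in_convex_hull(self, casa):
        spec = GroupSpec(delta=[0.0, 0.25, 0.75, 1.0], fractions=[0.1, 0.2, 0.3, 0.4])
        mg = solve_multigroup(spec, casa)
        stack = np.array([r.x_star for r in mg.groups])
        assert np.all(mg.population >= stack.min(axis=0) - 1e-14)
        assert np.all(mg.population <= stack.max(axis=0) + 1e-14)

    def test_equal_severities_coincide(self, casa):
        spec = GroupSpec(delta=[0.4, 0.4, 0.4], fractions=[0.2, 0.3, 0.5])
        mg = solve_multigroup(spec, casa)
        for r in mg.groups[1:]:
            np.testing.assert_array_equal(r.x_star, mg.groups[0].x_star)

    def test_permuting_groups_permutes_results(self, casa):
        a = solve_multigroup(GroupSpec(delta=[0.1, 0.9], fractions=[0.3, 0.7]), casa)
        b = solve_multigroup(GroupSpec(delta=[0.9, 0.1], fractions=[0.7, 0.3]), casa)
        np.testing.assert_array_equal(a.groups[0].x_star, b.groups[1].x_star)
        np.testing.assert_array_equal(a.groups[1].x_star, b.groups[0].x_star)
        np.testing.assert_allclose(a.population, b.population, atol=1e-15)
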