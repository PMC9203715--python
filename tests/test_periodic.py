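import numpy as np
import pytest

from quadtrot.params import ModelParams
from quadtrot.periodic import (
    PeriodicSolutionNotFound,
    analyze_stability,
    find_periodic,
    poincare_jacobian,
    poincare_map,
    stability,
)


class TestFixedPoint:
    def test_symmetric_dog_solution(self, dog_sym_solution):
        sol = dog_sym_solution
        assert sol.residual < 1e-8
        assert sol.sequence.sequence_id == 1
        assert sol.tau_half == pytest.approx(1.75, abs=0.02)
        # anti-symmetric: th_F = -th_H, thdot_F = -thdot_H
        x = sol.x_star
        assert x[1] == pytest.approx(-x[2], abs=1e-8)
        assert x[3] == pytest.approx(-x[4], abs=1e-8)

    def test_fixed_point_maps_to_itself(self, dog_solution):
        x1 = poincare_map(dog_solution.x_star, dog_solution.params)
        np.testing.assert_allclose(x1, dog_solution.x_star, atol=1e-8)
        x2 = poincare_map(x1, dog_solution.params)
        np.testing.assert_allclose(x2, dog_solution.x_star, atol=1e-7)

    def test_map_preserves_energy(self, dog):
        from quadtrot.dynamics import FLIGHT, energy, full_state

        p, z_star = dog
        x = np.array([z_star, 0.05, -0.08, -0.9, 0.8])
        x1 = poincare_map(x, p)
        q0 = full_state(x[0], x[1], x[2], 0.0, x[3], x[4])
        q1 = full_state(x1[0], x1[1], x1[2], 0.0, x1[3], x1[4])
        assert energy(q0, FLIGHT, p) == pytest.approx(
            energy(q1, FLIGHT, p), abs=1e-8
        )

    def test_continuation_into_asymmetry_gives_fore_led_sequence(
        self, dog_sym_solution
    ):
        p = dog_sym_solution.params.replace(eps_k=0.01)
        sol = find_periodic(p, 0.06, x_guess=dog_sym_solution.x_star)
        assert sol.sequence.sequence_id == 5

    def test_residual_survives_tighter_integration(self, dog_solution):
        """The fixed point is not an artifact of the integration tolerance."""
        x = dog_solution.x_star
        x1 = poincare_map(x, dog_solution.params, rtol=1e-11, atol=1e-13)
        assert np.max(np.abs(x - x1)) < 1e-7

    def test_invalid_apex_height_rejected(self, dog):
        p, _ = dog
        with pytest.raises(ValueError):
            find_periodic(p, -0.01)

    def test_not_found_carries_best_residual(self):
        # hopelessly stiff, tiny apex: the seed ladder cannot converge fast
        p = ModelParams(mu0=0.62, k0=1.5, kappa=0.2)
        with pytest.raises(PeriodicSolutionNotFound) as exc:
            find_periodic(p, 0.06, x_guess=np.array([0.06, 0.5, -0.5, 3.0, 3.0]),
                          residual_tol=1e-30)
        assert exc.value.best_residual > 0


class TestJacobianAndStability:
    def test_stability_of_trivial_matrices(self):
        lam, stable = stability(np.eye(5))
        assert lam == pytest.approx(1.0) and stable
        lam, stable = stability(np.diag([2.0, 0, 0, 0, 0]))
        assert lam == pytest.approx(2.0) and not stable

    def test_jacobian_richardson_convergence(self, dog_solution):
        """Central differences are second order: halving h changes J by
        O(h^2), so the two estimates agree to ~1e-6."""
        J1 = poincare_jacobian(dog_solution.x_star, dog_solution.params, h=2e-6)
        J2 = poincare_jacobian(dog_solution.x_star, dog_solution.params, h=1e-6)
        assert np.max(np.abs(J1 - J2)) < 1e-6

    def test_unit_eigenvalue_on_energy_family(self, dog_solution):
        sol = analyze_stability(dog_solution)
        assert np.min(np.abs(sol.eigenvalues - 1.0)) < 1e-3

    def test_no_asymptotic_stability(self, dog_solution, horse_solution):
        for sol in (dog_solution, horse_solution):
            sol = analyze_stability(sol)
            assert sol.Lambda >= 1.0 - 1e-3

    def test_symmetric_dog_marginally_stable(self, dog_sym_solution):
        sol = analyze_stability(dog_sym_solution)
        assert sol.Lambda == pytest.approx(1.0, abs=1e-3)
        assert sol.stable

    def test_horse_preset_sits_on_stability_knife_edge(self, horse_sym_solution):
        """The symmetric horse base (mu0=0.72, k0=2.2, kappa=0.21) is
        marginally stable, but instability is one small parameter nudge
        away: lowering kappa to 0.195 or raising mu0 to 0.73 destabilizes."""
        sol = analyze_stability(horse_sym_solution)
        assert sol.Lambda == pytest.approx(1.0, abs=1e-3)
        low_kappa = analyze_stability(
            find_periodic(ModelParams(mu0=0.72, k0=2.2, kappa=0.195), 0.06)
        )
        assert low_kappa.Lambda > 1.05
        high_mu = analyze_stability(
            find_periodic(ModelParams(mu0=0.73, k0=2.2, kappa=0.21), 0.06)
        )
        assert high_mu.Lambda > 1.05

    def test_high_inertia_symmetric_model_unstable(self):
        """Well above the mu0 = kappa + 1/2 boundary the symmetric trot
        loses stability with a clearly expanding Floquet multiplier."""
        p = ModelParams(mu0=0.9, k0=1.5, kappa=0.2)
        sol = analyze_stability(find_periodic(p, 0.06))
        assert sol.Lambda > 1.05
        assert not sol.stable


class TestPerturbationDynamics:
    def test_stable_orbit_confines_perturbations(self, dog_solution):
        p = dog_solution.params
        x_star = dog_solution.x_star
        x = x_star + 1e-4 * np.array([1.0, -0.5, 0.7, 0.4, -0.8]) / np.sqrt(2.3)
        for _ in range(50):
            x = poincare_map(x, p, rtol=1e-9, atol=1e-11)
        assert np.linalg.norm(x - x_star) < 1e-2

    def test_unstable_orbit_expels_perturbations(self):
        p = ModelParams(mu0=0.9, k0=1.5, kappa=0.2)
        sol = find_periodic(p, 0.06)
        x = sol.x_star + 1e-4 * np.array([0.0, 1.0, 1.0, 0.5, 0.5]) / 1.66
        drift = 0.0
        for _ in range(50):
            try:
                x = poincare_map(x, p, rtol=1e-9, atol=1e-11)
            except Exception:
                drift = np.inf  # left the trot automaton entirely
                break
            drift = np.linalg.norm(x - sol.x_star)
            if drift > 1e-1:
                break
        assert drift > 1e-1
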