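"""Equilibrium solves, feasibility, Jacobian and the ODE cross-check."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from lvfeas.config import CommunityConfig
from lvfeas.equilibrium import (DegenerateEquilibriumError,
                                community_jacobian, is_feasible,
                                lv_derivative, solve_equilibrium,
                                structural_growth_rates)
from lvfeas.experiments import draw_community, structural_vector
from lvfeas.interactions import normalization_factor

A2 = np.array([[0.0, 0.5], [-0.5, 0.0]])  # hand-solvable 2-species system


def test_zero_interactions_give_unit_abundances():
    eq = solve_equilibrium(np.zeros((4, 4)), np.ones(4), -1.0, 0.25, 4, 0.5)
    np.testing.assert_allclose(eq.x_star, np.ones(4))
    assert eq.feasible and not eq.degenerate


def test_two_species_feasible_hand_solution():
    eq = solve_equilibrium(A2, np.array([-0.25, 1.0]), -1.0, 0.5, 2, 0.0)
    np.testing.assert_allclose(eq.x_star, [0.2, 0.9], atol=1e-12)
    assert eq.feasible
    assert is_feasible(eq)


def test_two_species_infeasible_hand_solution():
    # hand 2x2 solve: -x1 + 0.5*x2 = -1, -0.5*x1 - x2 = 0.2
    eq = solve_equilibrium(A2, np.array([1.0, -0.2]), -1.0, 0.5, 2, 0.0)
    np.testing.assert_allclose(eq.x_star, [0.72, -0.56], atol=1e-12)
    assert not eq.feasible
    assert not is_feasible(eq)


def test_exact_zero_abundance_is_infeasible():
    # A=0, theta=-1: x* = r, so a zero growth rate gives an exact zero
    eq = solve_equilibrium(np.zeros((2, 2)), np.array([0.0, 1.0]),
                           -1.0, 0.5, 2, 0.0)
    assert eq.x_star[0] == 0.0
    assert not is_feasible(eq)


def test_singular_system_flags_degenerate():
    A = np.array([[0.0, 1.0], [1.0, 0.0]])  # theta*I + A singular at theta=-1
    eq = solve_equilibrium(A, np.ones(2), -1.0, 0.5, 2, 0.0)
    assert eq.degenerate
    with pytest.raises(DegenerateEquilibriumError):
        is_feasible(eq)
    with pytest.raises(DegenerateEquilibriumError):
        community_jacobian(eq, A, -1.0, 0.5, 2, 0.0)


def test_jacobian_hand_example():
    eq = solve_equilibrium(A2, np.array([-0.25, 1.0]), -1.0, 0.5, 2, 0.0)
    J = community_jacobian(eq, A2, -1.0, 0.5, 2, 0.0)
    np.testing.assert_allclose(J, [[-0.2, 0.1], [-0.45, -0.9]], atol=1e-12)


def test_jacobian_rows_scale_with_abundance():
    eq = solve_equilibrium(A2, np.array([-0.25, 1.0]), -1.0, 0.5, 2, 0.0)
    J = community_jacobian(eq, A2, -1.0, 0.5, 2, 0.0)
    B = -np.eye(2) + A2
    np.testing.assert_allclose(J, eq.x_star[:, None] * B)


def test_lv_derivative_vanishes_at_equilibrium(rng):
    cfg = CommunityConfig(S=20, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                          model="may", seed=11)
    _, im = draw_community(cfg, rng)
    r = structural_vector(cfg)
    eq = solve_equilibrium(im, r, -1.0, 0.25, 20, 0.5)
    assert not eq.degenerate
    dx = lv_derivative(eq.x_star, r, -1.0, 0.25, 20, 0.5, im)
    assert np.abs(dx).max() < 1e-9


def test_lv_derivative_extinction_and_logistic():
    A = np.zeros((2, 2))
    np.testing.assert_array_equal(
        lv_derivative(np.zeros(2), np.ones(2), -1.0, 0.5, 2, 0.0, A),
        np.zeros(2))
    A1 = np.zeros((1, 1))
    dx = lv_derivative([0.5], [1.0], -1.0, 0.5, 1, 0.0, A1)
    assert dx[0] == pytest.approx(0.25)  # logistic growth 0.5*(1-0.5)


def test_structural_rates_may_model_are_all_ones():
    r = structural_growth_rates(np.zeros((5, 5)), -1.0, 0.25, 5, 0.5)
    np.testing.assert_allclose(r, np.ones(5))


def test_structural_rates_mutualism_row_sum():
    """Uniform off-diagonal mean m gives r_i = |theta| - 2*f*m at S=3."""
    m = 0.07978845608028654  # C*sigma*sqrt(2/pi) for C=0.25, sigma=0.4
    A_bar = np.full((3, 3), m)
    np.fill_diagonal(A_bar, 0.0)
    f = normalization_factor(0.25, 3, 0.5)
    r = structural_growth_rates(A_bar, -1.0, 0.25, 3, 0.5)
    np.testing.assert_allclose(r, np.full(3, 1.0 - 2 * f * m))


def test_structural_rates_structured_webs_contain_negative_entries():
    """Predators starve without prey: trophic structural vectors contain
    negative growth rates (visible under moderate scaling, where the
    per-link normalization leaves trophic row sums large)."""
    cfg = CommunityConfig(S=100, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                          model="niche", seed=5)
    r = structural_vector(cfg)
    assert r.min() < 0 < r.max()


def test_structural_consistency_mean_field_equilibrium_is_ones():
    """Solving with the mean matrix and structural rates returns exactly
    the all-ones abundance vector."""
    from lvfeas.interactions import mean_interaction_matrix
    for model in ("may", "mutualism", "competition"):
        cfg = CommunityConfig(S=8, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                              model=model)
        A_bar = mean_interaction_matrix(cfg)
        r = structural_growth_rates(A_bar, -1.0, 0.25, 8, 0.5)
        eq = solve_equilibrium(A_bar, r, -1.0, 0.25, 8, 0.5)
        np.testing.assert_allclose(eq.x_star, np.ones(8), atol=1e-12)


def test_linear_solve_residual_invariant(rng):
    """||B x* + r||_inf stays below 1e-9 on random non-degenerate draws."""
    cfg = CommunityConfig(S=30, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                          model="may", seed=2)
    r = structural_vector(cfg)
    f = normalization_factor(0.25, 30, 0.5)
    for _ in range(30):
        _, im = draw_community(cfg, rng)
        eq = solve_equilibrium(im, r, -1.0, 0.25, 30, 0.5)
        if eq.degenerate:
            continue
        B = -np.eye(30) + f * im.A
        assert np.abs(B @ eq.x_star + r).max() < 1e-9


def test_ode_integration_converges_to_linear_solve(rng):
    """For small stable feasible systems, integrating the dynamics from a
    perturbed start returns to the linear-solve equilibrium."""
    from lvfeas.theory import spectral_stability
    checked = 0
    seed = 0
    while checked < 5 and seed < 60:
        cfg = CommunityConfig(S=5, C=0.4, delta=0.5, theta=-1.0, sigma=0.4,
                              model="may", seed=seed)
        seed += 1
        _, im = draw_community(cfg, np.random.default_rng(seed))
        r = structural_vector(cfg)
        eq = solve_equilibrium(im, r, -1.0, 0.4, 5, 0.5)
        if eq.degenerate or not eq.feasible:
            continue
        J = community_jacobian(eq, im, -1.0, 0.4, 5, 0.5)
        if not spectral_stability(J)[0]:
            continue
        x0 = np.clip(eq.x_star * (1 + 0.05 * rng.standard_normal(5)),
                     1e-8, None)
        sol = solve_ivp(
            lambda t, x: lv_derivative(np.clip(x, 0.0, None), r, -1.0,
                                       0.4, 5, 0.5, im),
            (0.0, 600.0), x0, rtol=1e-10, atol=1e-10)
        assert np.abs(sol.y[:, -1] - eq.x_star).max() < 1e-6
        checked += 1
    assert checked == 5
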