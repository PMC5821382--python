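"""Lotka-Volterra equilibria, feasibility and the community Jacobian.

The community obeys dx_i/dt = x_i (r_i + theta x_i + (CS)^(−delta)
(A x)_i). Writing B = theta·I + (CS)^(−delta)·A, the interior equilibrium
solves B x* = −r; it is *feasible* when every component of x* is strictly
positive. The Jacobian at x* is diag(x*)·B (the community matrix).

Draws for which B is numerically near-singular — which happens when the
strength scale sigma approaches |theta| and the system becomes structurally
unstable — are flagged *degenerate* rather than silently counted either
way, since their solved abundances are dominated by near-zero eigenvalues
of B and carry no feasibility information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import get_lapack_funcs, lu_factor, lu_solve

from .interactions import InteractionMatrix, normalization_factor

__all__ = [
    "Equilibrium",
    "DegenerateEquilibriumError",
    "structural_growth_rates",
    "solve_equilibrium",
    "is_feasible",
    "community_jacobian",
    "lv_derivative",
    "COND_THRESHOLD",
]

#: conditioning threshold beyond which a draw is declared degenerate
COND_THRESHOLD = 1e12

#: infinity-norm residual tolerance for ||B x* + r|| on accepted solves
RESIDUAL_TOL = 1e-9


class DegenerateEquilibriumError(RuntimeError):
    """Raised when an operation requires a non-degenerate equilibrium."""


@dataclass(frozen=True)
class Equilibrium:
    """Solved equilibrium abundances with diagnostics.

    ``condition_estimate`` is a 1-norm condition-number estimate of
    B = theta·I + (CS)^(−delta)·A; ``degenerate`` marks draws where it
    exceeds :data:`COND_THRESHOLD` (or B is exactly singular), in which
    case ``x_star`` is NaN and ``feasible`` is False.
    """

    x_star: np.ndarray
    feasible: bool
    condition_estimate: float
    degenerate: bool


def _as_matrix(A) -> np.ndarray:
    if isinstance(A, InteractionMatrix):
        return A.A
    return np.asarray(A, dtype=float)


def _system_matrix(A, theta, C, S, delta) -> np.ndarray:
    if theta >= 0:
        raise ValueError("theta must be negative")
    Amat = _as_matrix(A)
    if Amat.shape != (S, S):
        raise ValueError(f"A must be {S}x{S}, got {Amat.shape}")
    f = normalization_factor(C, S, delta)
    B = f * Amat
    B[np.diag_indices(S)] += theta
    return B


def structural_growth_rates(A_bar, theta: float, C: float, S: int,
                            delta: float) -> np.ndarray:
    """Mean structural growth-rate vector.

    r = −(theta·I + (CS)^(−delta)·Ā)·1: the deterministic rates for which
    the *mean-field* equilibrium is exactly the all-ones vector, i.e. on
    average as far as possible from the boundary of the positive orthant.
    For trophically structured webs some entries come out negative —
    predators starve without prey.
    """
    B = _system_matrix(A_bar, theta, C, S, delta)
    return -B.sum(axis=1)


def solve_equilibrium(A, r, theta: float, C: float, S: int, delta: float,
                      cond_threshold: float = COND_THRESHOLD) -> Equilibrium:
    """Solve B x* = −r by dense LU with a conditioning guard.

    A singular or ill-conditioned system yields a degenerate Equilibrium
    (never an exception): degenerate draws are excluded from feasibility
    counts downstream but reported.
    """
    B = _system_matrix(A, theta, C, S, delta)
    r = np.asarray(r, dtype=float)
    if r.shape != (S,):
        raise ValueError(f"r must have length {S}")

    anorm = np.abs(B).sum(axis=0).max()  # 1-norm
    try:
        lu, piv = lu_factor(B)
    except (np.linalg.LinAlgError, ValueError):
        return Equilibrium(np.full(S, np.nan), False, np.inf, True)
    gecon, = get_lapack_funcs(("gecon",), (B,))
    rcond, info = gecon(lu, anorm, norm="1")
    cond = np.inf if rcond == 0 else 1.0 / rcond
    if info != 0 or not np.isfinite(cond) or cond > cond_threshold:
        return Equilibrium(np.full(S, np.nan), False, float(cond), True)

    x = lu_solve((lu, piv), -r)
    resid = np.abs(B @ x + r).max()
    scale = max(1.0, np.abs(r).max(), np.abs(x).max())
    if not np.isfinite(x).all() or resid > RESIDUAL_TOL * scale:
        return Equilibrium(np.full(S, np.nan), False, float(cond), True)
    return Equilibrium(x, bool(np.all(x > 0.0)), float(cond), False)


def is_feasible(eq: Equilibrium) -> bool:
    """True iff every equilibrium abundance is strictly positive.

    Exact zeros count as infeasible; degenerate equilibria have no defined
    feasibility and raise :class:`DegenerateEquilibriumError`.
    """
    if eq.degenerate:
        raise DegenerateEquilibriumError(
            "feasibility is undefined for a degenerate (ill-conditioned) "
            "equilibrium")
    return bool(np.all(eq.x_star > 0.0))


def community_jacobian(eq: Equilibrium, A, theta: float, C: float, S: int,
                       delta: float) -> np.ndarray:
    """Community matrix J(x*) = diag(x*)·(theta·I + (CS)^(−delta)·A)."""
    if eq.degenerate:
        raise DegenerateEquilibriumError(
            "the Jacobian is undefined for a degenerate equilibrium")
    B = _system_matrix(A, theta, C, S, delta)
    return eq.x_star[:, None] * B


def lv_derivative(x, r, theta: float, C: float, S: int, delta: float,
                  A) -> np.ndarray:
    """Right-hand side x ∘ (r + B x) of the Lotka-Volterra system."""
    B = _system_matrix(A, theta, C, S, delta)
    x = np.asarray(x, dtype=float)
    r = np.asarray(r, dtype=float)
    return x * (r + B @ x)
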