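"""Closed-form feasibility and stability theory for large random communities.

Implements the interaction-strength regime classification, May's stability
condition for the linkage-density-normalized model, direct spectral
stability of the community matrix, and the asymptotic feasibility theory
for the moderate and weak regimes:

* moderate regime (delta = 1/2), sigma < |theta|: equilibrium abundances
  are asymptotically i.i.d. N(mu*, sigma*²), so with the mean structural
  vector P_S ≈ Phi(sqrt((theta² − sigma²)/sigma²))^S — a power-law decay
  to zero in species richness;
* weak regime (delta > 1/2): abundances concentrate on a deterministic
  vector and P_S tends to 1 or 0 according to whether every growth rate
  exceeds the threshold r̄·mu_A/(mu_A + theta).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "Regime",
    "ModerateTheory",
    "classify_regime",
    "may_stability_condition",
    "spectral_stability",
    "analytic_feasibility_probability",
    "moderate_regime_moments",
    "weak_regime_limit",
]


@dataclass(frozen=True)
class Regime:
    """Interaction-strength regime for a given exponent delta."""

    label: str  # "strong" | "moderate" | "weak"
    delta: float


@dataclass(frozen=True)
class ModerateTheory:
    """Asymptotic abundance moments and feasibility in the moderate regime."""

    mu_star: float
    sigma_star_sq: float
    p_s: float


def classify_regime(delta: float) -> Regime:
    """Strong (0 <= delta < 1/2), moderate (= 1/2) or weak (> 1/2).

    delta = 1/2 is compared exactly as entered, with no tolerance: the
    moderate regime is a single point, the only scaling under which May's
    criterion is independent of S and C.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta must lie in [0, 1], got {delta!r}")
    if delta < 0.5:
        label = "strong"
    elif delta == 0.5:
        label = "moderate"
    else:
        label = "weak"
    return Regime(label, float(delta))


def may_stability_condition(sigma: float, C: float, S: int, delta: float,
                            theta: float) -> bool:
    """May's criterion sigma·(CS)^(−delta)·sqrt(CS) < |theta|.

    At delta = 1/2 the left side reduces to sigma, so the verdict depends
    on sigma and theta alone; for delta < 1/2 it grows with S and the
    criterion eventually fails as richness increases.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if C * S <= 0:
        raise ValueError("C*S must be positive")
    if theta >= 0:
        raise ValueError("theta must be negative")
    return bool(sigma * (C * S) ** (0.5 - delta) < abs(theta))


def spectral_stability(J) -> tuple[bool, float]:
    """(stable?, leading eigenvalue real part) of a community matrix.

    Stable iff the maximal real part is strictly negative; a leading real
    part of exactly zero reports unstable (no tolerance band).
    """
    J = np.asarray(J, dtype=float)
    if J.ndim != 2 or J.shape[0] != J.shape[1]:
        raise ValueError("J must be square")
    if not np.isfinite(J).all():
        raise ValueError("J contains non-finite entries")
    lead = float(np.linalg.eigvals(J).real.max())
    return lead < 0.0, lead


def analytic_feasibility_probability(S: int, sigma: float,
                                     theta: float) -> float:
    """Closed-form P_S = Phi(sqrt((theta² − sigma²)/sigma²))^S.

    Valid in the moderate regime (delta = 1/2) with growth rates set to the
    mean structural vector and 0 < sigma < |theta|; at sigma >= |theta| the
    system is structurally unstable and no asymptotic feasibility
    probability is defined.
    """
    if S < 1:
        raise ValueError("S must be >= 1")
    if not (0.0 < sigma < abs(theta)):
        raise ValueError(
            "analytic P_S requires 0 < sigma < |theta| "
            f"(structural stability); got sigma={sigma!r}, theta={theta!r}")
    z = np.sqrt((theta ** 2 - sigma ** 2) / sigma ** 2)
    return float(np.exp(S * norm.logcdf(z)))


def moderate_regime_moments(r_bar: float, sigma_r_sq: float, sigma: float,
                            theta: float) -> tuple[float, float]:
    """Asymptotic abundance mean and variance in the moderate regime.

    With i.i.d. growth rates of mean r̄ and variance sigma_r², and
    sigma < |theta|, each x*_i is asymptotically N(mu*, sigma*²) with

        mu* = −r̄/theta,
        sigma*² = sigma_r²/theta² + r²·sigma² / (theta²·(theta² − sigma²)),

    where r² = sigma_r² + r̄² is the second moment of the rates.
    """
    if sigma_r_sq < 0:
        raise ValueError("sigma_r_sq must be non-negative")
    if not (0.0 <= sigma < abs(theta)):
        raise ValueError("moments require sigma < |theta|")
    mu_star = -r_bar / theta
    r_sq = sigma_r_sq + r_bar ** 2
    sigma_star_sq = (sigma_r_sq / theta ** 2
                     + r_sq * sigma ** 2
                     / (theta ** 2 * (theta ** 2 - sigma ** 2)))
    return float(mu_star), float(sigma_star_sq)


def weak_regime_limit(r, mu_A: float, theta: float) -> int:
    """Predicted limit of P_S (0 or 1) under weak interactions.

    P_S → 1 when every growth rate exceeds r̄·mu_A/(mu_A + theta), with r̄
    the sample mean of the rates; otherwise P_S → 0. In May's framework
    (mu_A = 0) this reduces to: all growth rates positive.
    """
    if mu_A + theta == 0:
        raise ValueError("threshold undefined when mu_A + theta == 0")
    r = np.asarray(r, dtype=float)
    threshold = r.mean() * mu_A / (mu_A + theta)
    return 1 if r.min() > threshold else 0
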