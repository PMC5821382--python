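"""Signed random interaction strengths on a topology.

The interaction matrix A collects per-capita effects a_ij supported on the
adjacency. Four sign structures are available:

* ``may_mixture`` — every supported entry i.i.d. N(0, sigma): a mixture of
  interaction types including commensalism and amensalism (May's model);
  requires a directed unstructured topology.
* ``mutualism`` / ``competition`` — every supported entry an independent
  folded Gaussian |N(0, sigma)| with sign + / −; requires a paired topology.
* ``predation`` — sign(a_ij) = −sign(a_ji) on every linked pair. On a
  paired topology a fair coin picks the predator of each pair; on a
  structured topology the stored direction is the predator side:
  A = |N| on alpha plus −|N| on alpha^T, with independent magnitudes.

Before entering the dynamics, A is scaled by the linkage-density factor
(C·S)^(−delta); see :func:`normalization_factor`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .networks import STRUCTURED_TAGS, Topology

__all__ = [
    "InteractionMatrix",
    "normalization_factor",
    "sample_interaction_matrix",
    "mean_interaction_matrix",
    "mean_pairwise_strength",
    "INTERACTION_TYPES",
]

INTERACTION_TYPES = frozenset(
    {"may_mixture", "mutualism", "competition", "predation"})

_COMPAT = {
    "may_mixture": {"may_directed"},
    "mutualism": {"unstructured_paired"},
    "competition": {"unstructured_paired"},
    "predation": {"unstructured_paired"} | STRUCTURED_TAGS,
}


@dataclass(frozen=True)
class InteractionMatrix:
    """Realized signed interaction strengths on a topology."""

    A: np.ndarray
    interaction_type: str
    sigma: float
    topology: Topology


def normalization_factor(C: float, S: int, delta: float) -> float:
    """Interaction-strength scaling (C·S)^(−delta).

    The linkage density C·S measures complexity; dividing the raw strengths
    by its delta-th power defines the strong (delta < 1/2), moderate
    (delta = 1/2) and weak (delta > 1/2) interaction regimes.
    """
    if not (0.0 <= delta <= 1.0):
        raise ValueError(f"delta must lie in [0, 1], got {delta!r}")
    if C * S <= 0:
        raise ValueError("C*S must be positive")
    return float((C * S) ** (-delta))


def _check_type(interaction_type: str, t: Topology) -> None:
    if interaction_type not in INTERACTION_TYPES:
        raise ValueError(f"unknown interaction type {interaction_type!r}")
    if t.model_tag not in _COMPAT[interaction_type]:
        raise ValueError(
            f"interaction type {interaction_type!r} is incompatible with "
            f"topology model {t.model_tag!r}")


def sample_interaction_matrix(t: Topology, interaction_type: str,
                              sigma: float,
                              rng: np.random.Generator | None = None
                              ) -> InteractionMatrix:
    """Draw a random interaction matrix supported on topology ``t``."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    _check_type(interaction_type, t)
    rng = np.random.default_rng(rng)
    S = t.S
    a = t.alpha.astype(bool)
    A = np.zeros((S, S))

    if interaction_type == "may_mixture":
        A[a] = rng.normal(0.0, sigma, size=int(a.sum()))
    elif interaction_type in ("mutualism", "competition"):
        mags = np.abs(rng.normal(0.0, sigma, size=int(a.sum())))
        A[a] = mags if interaction_type == "mutualism" else -mags
    elif t.model_tag in STRUCTURED_TAGS:
        # stored direction = predator side (i preys on j)
        A[a] = np.abs(rng.normal(0.0, sigma, size=int(a.sum())))
        A[a.T] = -np.abs(rng.normal(0.0, sigma, size=int(a.sum())))
    else:
        iu, ju = np.nonzero(np.triu(t.alpha, k=1))
        for i, j in zip(iu, ju):
            pred, prey = (i, j) if rng.random() < 0.5 else (j, i)
            A[pred, prey] = abs(rng.normal(0.0, sigma))
            A[prey, pred] = -abs(rng.normal(0.0, sigma))
    return InteractionMatrix(A, interaction_type, float(sigma), t)


def mean_pairwise_strength(interaction_type: str, sigma: float) -> float:
    """Expected strength mu_A of a nonzero interaction coefficient.

    Zero for May's mixture and for predation (predator/prey symmetry),
    ±sigma*sqrt(2/pi) (the folded-normal mean) for mutualism/competition.
    """
    if interaction_type in ("may_mixture", "predation"):
        return 0.0
    m = sigma * math.sqrt(2.0 / math.pi)
    if interaction_type == "mutualism":
        return m
    if interaction_type == "competition":
        return -m
    raise ValueError(f"unknown interaction type {interaction_type!r}")


def mean_interaction_matrix(config, M: int | None = None,
                            rng: np.random.Generator | None = None,
                            method: str = "auto") -> np.ndarray:
    """Unconditional mean Ā of the interaction matrix under a config.

    Averages over both the random topology and the random strengths. For
    unstructured models a closed form exists (zero for May's mixture and
    paired predation, ±C·sigma·sqrt(2/pi) off-diagonal for mutualism /
    competition); structured models are averaged over ``M`` Monte-Carlo
    draws (default: ``config.M``, conventionally 200).

    ``method`` is ``"auto"`` (closed form when available), ``"closed_form"``
    or ``"mc"``.
    """
    from .experiments import draw_community  # deferred: avoid import cycle

    S, C, sigma = config.S, config.C, config.sigma
    itype = config.interaction_type
    if method not in ("auto", "closed_form", "mc"):
        raise ValueError(f"unknown method {method!r}")

    closed_available = config.model in ("may", "mutualism", "competition",
                                        "predation")
    if method == "closed_form" and not closed_available:
        raise ValueError(
            f"no closed-form mean for structured model {config.model!r}")
    if method in ("auto", "closed_form") and closed_available:
        if itype in ("may_mixture", "predation"):
            return np.zeros((S, S))
        A_bar = np.full((S, S), C * mean_pairwise_strength(itype, sigma))
        np.fill_diagonal(A_bar, 0.0)
        return A_bar

    M = int(config.M if M is None else M)
    if M < 1:
        raise ValueError("M must be >= 1")
    rng = np.random.default_rng(rng)
    acc = np.zeros((S, S))
    for _ in range(M):
        _, im = draw_community(config, rng)
        acc += im.A
    return acc / M
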