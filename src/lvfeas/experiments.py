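"""Monte-Carlo estimation of feasibility probabilities and abundance
statistics across network models, interaction regimes and species richness.

Each replicate draws a fresh topology and interaction matrix under a
:class:`~lvfeas.config.CommunityConfig`, solves the linear equilibrium, and
records strict feasibility. Ill-conditioned (degenerate) draws are excluded
from both numerator and denominator of the feasibility estimate and
reported in their own count. Growth rates specified as i.i.d. random are
resampled per replicate; the mean structural vector is computed once per
configuration.

Seeding: replicate k of a run at richness S uses a stream derived from
(base seed, S, k), so curves are reproducible point-by-point and can be
extended without recomputing earlier points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from ._rng import spawn_rng
from .config import CommunityConfig, GrowthRateSpec
from .equilibrium import solve_equilibrium, structural_growth_rates, \
    community_jacobian
from .interactions import mean_interaction_matrix, sample_interaction_matrix
from .networks import STRUCTURED_TAGS, generate_cascade, generate_niche, \
    generate_nested_hierarchy, generate_unstructured, trophic_roles
from .theory import analytic_feasibility_probability, spectral_stability

__all__ = [
    "PSEstimate",
    "AbundanceSummary",
    "StabilityReport",
    "EstimateUndefinedError",
    "draw_community",
    "draw_growth_rates",
    "iter_replicates",
    "structural_vector",
    "estimate_feasibility",
    "feasibility_curve",
    "abundance_summary",
    "stability_given_feasibility",
]

logger = logging.getLogger(__name__)

#: fraction of degenerate draws above which an experiment warns loudly
DEGENERATE_WARN_FRACTION = 0.05


class EstimateUndefinedError(RuntimeError):
    """Raised when every draw of an experiment was degenerate."""


@dataclass(frozen=True)
class PSEstimate:
    """Estimated feasibility probability with a 95% confidence interval."""

    n_total: int
    n_degenerate: int
    n_feasible: int
    p_hat: float
    ci_low: float
    ci_high: float
    config: CommunityConfig

    @property
    def n_effective(self) -> int:
        return self.n_total - self.n_degenerate


@dataclass(frozen=True)
class AbundanceSummary:
    """Per-species equilibrium abundance statistics across replicates.

    ``table`` has one row per species: columns ``species`` (1-based,
    hierarchy order), ``rank`` (0 = top, 1 = basal), ``role`` (modal
    trophic role across replicate webs), ``mean``, ``sd``, ``min``,
    ``max``. ``role_sd`` maps each role to the average of per-species sds
    within that role.
    """

    table: pd.DataFrame
    role_sd: dict
    n_replicates: int
    config: CommunityConfig


@dataclass(frozen=True)
class StabilityReport:
    """Spectral stability conditioned on feasibility."""

    n_total: int
    n_degenerate: int
    n_feasible: int
    n_stable_given_feasible: int
    fraction_stable_given_feasible: float | None
    leading_real_feasible: np.ndarray
    leading_real_infeasible: np.ndarray
    config: CommunityConfig


def draw_community(config: CommunityConfig, rng: np.random.Generator):
    """Draw one (Topology, InteractionMatrix) pair under a config."""
    m = config.model
    if m == "may":
        t = generate_unstructured(config.S, config.C, "directed", rng)
    elif m in ("mutualism", "competition", "predation"):
        t = generate_unstructured(config.S, config.C, "paired", rng)
    elif m == "cascade":
        t = generate_cascade(config.S, config.C, rng)
    elif m == "niche":
        t = generate_niche(config.S, config.C, rng)
    else:
        t = generate_nested_hierarchy(config.S, config.C, rng)
    im = sample_interaction_matrix(t, config.interaction_type,
                                   config.sigma, rng)
    return t, im


def structural_vector(config: CommunityConfig,
                      rng: np.random.Generator | None = None) -> np.ndarray:
    """Mean structural growth-rate vector for a configuration.

    Uses the unconditional mean interaction matrix: closed form for
    unstructured models, a ``config.M``-draw Monte-Carlo average for
    structured ones (the Monte-Carlo stream derives from the config seed
    when no generator is given).
    """
    if rng is None:
        rng = spawn_rng(config.seed, "structural", config.S)
    A_bar = mean_interaction_matrix(config, rng=rng)
    return structural_growth_rates(A_bar, config.theta, config.C,
                                   config.S, config.delta)


def draw_growth_rates(config: CommunityConfig, rng: np.random.Generator,
                      structural: np.ndarray | None = None) -> np.ndarray:
    """Growth-rate vector for one replicate."""
    spec = config.rates
    if spec.kind == "structural":
        if structural is None:
            raise ValueError("structural rates must be precomputed")
        return structural
    if spec.kind == "iid_gaussian":
        return rng.normal(spec.mean, spec.sd, size=config.S)
    if spec.kind == "iid_uniform":
        return rng.uniform(spec.low, spec.high, size=config.S)
    v = np.asarray(spec.values, dtype=float)
    if v.shape != (config.S,):
        raise ValueError("fixed rates must have length S")
    return v


def iter_replicates(config: CommunityConfig, n_reps: int,
                    collect_roles: bool = False, jacobians: bool = False):
    """Replicate loop shared by all estimators.

    Yields one record per replicate with the solved ``"eq"`` and, on
    request, the draw's trophic ``"roles"`` and the Jacobian's spectral
    verdict (``"stable"``, ``"lead"``).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    structural = None
    if config.rates.kind == "structural":
        structural = structural_vector(config)
    log_every = max(1, n_reps // 10)
    for k in range(n_reps):
        if k % log_every == 0:
            logger.debug("replicate %d/%d (S=%d, model=%s)",
                         k, n_reps, config.S, config.model)
        rng = spawn_rng(config.seed, config.S, k)
        t, im = draw_community(config, rng)
        r = draw_growth_rates(config, rng, structural)
        eq = solve_equilibrium(im, r, config.theta, config.C, config.S,
                               config.delta)
        rec = {"eq": eq}
        if collect_roles:
            rec["roles"] = trophic_roles(t)
        if jacobians and not eq.degenerate:
            J = community_jacobian(eq, im, config.theta, config.C,
                                   config.S, config.delta)
            rec["stable"], rec["lead"] = spectral_stability(J)
        yield rec


def _warn_degenerate(n_deg: int, n_total: int) -> None:
    if n_deg > DEGENERATE_WARN_FRACTION * n_total:
        warnings.warn(
            f"{n_deg}/{n_total} draws were degenerate (ill-conditioned); "
            "estimates may be unreliable — sigma is likely too close to "
            "|theta|", RuntimeWarning, stacklevel=3)


def estimate_feasibility(config: CommunityConfig,
                         n_reps: int = 1000,
                         ci_method: str = "wilson") -> PSEstimate:
    """Monte-Carlo estimate of the feasibility probability P_S.

    Draws ``n_reps`` independent (topology, interactions, rates) triples,
    solves each equilibrium, and returns the fraction of strictly positive
    solutions among non-degenerate draws with a 95% confidence interval
    (Wilson score by default; ``ci_method="normal"`` gives the Wald
    interval).
    """
    n_feasible = n_deg = 0
    for rec in iter_replicates(config, n_reps):
        eq = rec["eq"]
        if eq.degenerate:
            n_deg += 1
        elif eq.feasible:
            n_feasible += 1
    n_eff = n_reps - n_deg
    if n_eff == 0:
        raise EstimateUndefinedError(
            "all draws were degenerate; P_S is undefined")
    _warn_degenerate(n_deg, n_reps)
    p_hat = n_feasible / n_eff
    ci_low, ci_high = proportion_confint(n_feasible, n_eff, alpha=0.05,
                                         method=ci_method)
    return PSEstimate(n_reps, n_deg, n_feasible, p_hat,
                      float(ci_low), float(ci_high), config)


def feasibility_curve(config: CommunityConfig, S_values,
                      n_reps: int = 1000,
                      ci_method: str = "wilson") -> pd.DataFrame:
    """Feasibility estimates over a grid of species richness values.

    Returns a tidy frame with one row per S: counts, p_hat, the 95% CI,
    and — when the configuration sits in the moderate regime with the
    structural vector and sigma < |theta| on an unstructured May model —
    the analytic prediction ``p_analytic``.
    """
    S_values = list(S_values)
    if not S_values or any(b <= a for a, b in zip(S_values, S_values[1:])):
        raise ValueError("S_values must be non-empty and increasing")
    rows = []
    for S in S_values:
        cfg = CommunityConfig(S=int(S), C=config.C, delta=config.delta,
                              theta=config.theta, sigma=config.sigma,
                              model=config.model, rates=config.rates,
                              M=config.M, seed=config.seed,
                              delta_str=config.delta_str)
        est = estimate_feasibility(cfg, n_reps, ci_method)
        p_analytic = np.nan
        if (config.model == "may" and config.delta == 0.5
                and config.rates.kind == "structural"
                and 0 < config.sigma < abs(config.theta)):
            p_analytic = analytic_feasibility_probability(
                int(S), config.sigma, config.theta)
        rows.append({"S": int(S), "n": est.n_total,
                     "n_feasible": est.n_feasible,
                     "n_degenerate": est.n_degenerate,
                     "p_hat": est.p_hat, "ci_low": est.ci_low,
                     "ci_high": est.ci_high, "p_analytic": p_analytic})
    return pd.DataFrame(rows)


def abundance_summary(config: CommunityConfig,
                      n_reps: int = 1000) -> AbundanceSummary:
    """Per-species equilibrium abundance statistics across replicates.

    Collects x* over all non-degenerate draws (feasible or not), annotates
    each species with its modal trophic role across the replicate webs and
    its hierarchy rank, and pools per-species standard deviations within
    role by averaging them.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    predation = config.model in ("cascade", "niche", "nested_hierarchy",
                                 "predation")
    xs, role_draws = [], []
    n_deg = 0
    for rec in iter_replicates(config, n_reps, collect_roles=predation):
        if rec["eq"].degenerate:
            n_deg += 1
            continue
        xs.append(rec["eq"].x_star)
        if predation:
            role_draws.append(rec["roles"].roles)
    if not xs:
        raise EstimateUndefinedError("all draws were degenerate")
    _warn_degenerate(n_deg, n_reps)
    X = np.asarray(xs)
    S = config.S
    if predation:
        role_arr = np.asarray(role_draws)
        modal = []
        for i in range(S):
            vals, counts = np.unique(role_arr[:, i], return_counts=True)
            modal.append(str(vals[np.argmax(counts)]))
        ranks = 1.0 - np.arange(S) / (S - 1)
    else:
        modal = ["unstructured"] * S
        ranks = np.full(S, np.nan)
    sds = X.std(axis=0, ddof=1)
    table = pd.DataFrame({
        "species": np.arange(1, S + 1),
        "rank": ranks,
        "role": modal,
        "mean": X.mean(axis=0),
        "sd": sds,
        "min": X.min(axis=0),
        "max": X.max(axis=0),
    })
    role_sd = {role: float(sds[np.asarray(modal) == role].mean())
               for role in sorted(set(modal))}
    return AbundanceSummary(table, role_sd, len(xs), config)


def stability_given_feasibility(config: CommunityConfig,
                                n_reps: int = 1000) -> StabilityReport:
    """Fraction of feasible equilibria that are spectrally stable.

    Also returns the leading Jacobian-eigenvalue real parts separately for
    feasible and infeasible (non-degenerate) draws; when no draw is
    feasible the conditional fraction is None and only the marginal
    spectra are reported.
    """
    n_deg = n_feas = n_stable = 0
    lead_f, lead_i = [], []
    for rec in iter_replicates(config, n_reps, jacobians=True):
        eq = rec["eq"]
        if eq.degenerate:
            n_deg += 1
            continue
        if eq.feasible:
            n_feas += 1
            n_stable += bool(rec["stable"])
            lead_f.append(rec["lead"])
        else:
            lead_i.append(rec["lead"])
    _warn_degenerate(n_deg, n_reps)
    frac = n_stable / n_feas if n_feas else None
    return StabilityReport(n_reps, n_deg, n_feas, n_stable, frac,
                           np.asarray(lead_f), np.asarray(lead_i), config)
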