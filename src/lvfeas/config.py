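"""Experiment configuration: community parameters and growth-rate specs.

A :class:`CommunityConfig` fully specifies one Monte-Carlo scenario:
species richness S, connectance C, interaction-strength exponent delta,
self-limitation theta (< 0), strength scale sigma, the network/interaction
model, the growth-rate specification, the structural-vector Monte-Carlo
trial count M, and the base seed. It is frozen and hashable so results can
be cached and manifests reproduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = ["GrowthRateSpec", "CommunityConfig", "MODELS",
           "model_interaction_type"]

MODELS = ("may", "mutualism", "competition", "predation",
          "cascade", "niche", "nested_hierarchy")

_MODEL_ITYPE = {
    "may": "may_mixture",
    "mutualism": "mutualism",
    "competition": "competition",
    "predation": "predation",
    "cascade": "predation",
    "niche": "predation",
    "nested_hierarchy": "predation",
}


def model_interaction_type(model: str) -> str:
    """Interaction sign structure implied by a community model tag."""
    try:
        return _MODEL_ITYPE[model]
    except KeyError:
        raise ValueError(f"unknown model {model!r}; "
                         f"choose one of {MODELS}") from None


@dataclass(frozen=True)
class GrowthRateSpec:
    """Intrinsic growth-rate specification.

    kind:
      * ``structural`` — the deterministic mean structural vector
        r = −(theta·I + (CS)^(−delta)·Ā)·1, which places the mean-field
        equilibrium at the all-ones abundance vector (as far as possible,
        on average, from the feasibility boundary).
      * ``iid_gaussian`` — r_i i.i.d. N(mean, sd²), resampled per replicate.
      * ``iid_uniform`` — r_i i.i.d. Uniform(low, high).
      * ``fixed`` — an explicit length-S vector.
    """

    kind: str = "structural"
    mean: float = 1.0
    sd: float = 0.0
    low: float = 0.0
    high: float = 1.0
    values: tuple = ()

    def __post_init__(self):
        kinds = ("structural", "iid_gaussian", "iid_uniform", "fixed")
        if self.kind not in kinds:
            raise ValueError(f"rates kind must be one of {kinds}, "
                             f"got {self.kind!r}")
        if self.kind == "iid_gaussian" and self.sd < 0:
            raise ValueError("sd must be non-negative")
        if self.kind == "iid_uniform" and not self.low < self.high:
            raise ValueError("iid_uniform requires low < high")
        if self.kind == "fixed" and len(self.values) == 0:
            raise ValueError("fixed rates require a non-empty vector")
        object.__setattr__(self, "values", tuple(float(v)
                                                 for v in self.values))

    def moments(self):
        """(mean, variance) of a single rate; fixed/structural vectors use
        their empirical moments when available."""
        if self.kind == "iid_gaussian":
            return self.mean, self.sd ** 2
        if self.kind == "iid_uniform":
            return (self.low + self.high) / 2, (self.high - self.low) ** 2 / 12
        if self.kind == "fixed":
            v = np.asarray(self.values)
            return float(v.mean()), float(v.var())
        raise ValueError("structural rates have no a-priori moments; "
                         "compute the vector first")


@dataclass(frozen=True)
class CommunityConfig:
    """Full specification of one feasibility experiment."""

    S: int
    C: float
    delta: float
    theta: float
    sigma: float
    model: str = "may"
    rates: GrowthRateSpec = field(default_factory=GrowthRateSpec)
    M: int = 200           # structural-vector Monte-Carlo trials
    seed: int = 0
    delta_str: str | None = None  # exact decimal form for manifests

    def __post_init__(self):
        if not isinstance(self.S, (int, np.integer)) or self.S < 2:
            raise ValueError(f"S must be an integer >= 2, got {self.S!r}")
        if not (0.0 < self.C < 1.0):
            raise ValueError(f"C must lie in (0, 1), got {self.C!r}")
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError(f"delta must lie in [0, 1], got {self.delta!r}")
        if self.theta >= 0:
            raise ValueError(f"theta must be negative, got {self.theta!r}")
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma!r}")
        model_interaction_type(self.model)  # validates model tag
        if self.M < 1:
            raise ValueError("M must be >= 1")
        if self.delta_str is None:
            object.__setattr__(self, "delta_str", repr(float(self.delta)))

    @property
    def interaction_type(self) -> str:
        return model_interaction_type(self.model)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["rates"] = asdict(self.rates)
        d["rates"]["values"] = list(self.rates.values)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CommunityConfig":
        d = dict(d)
        rates = d.get("rates", {})
        if isinstance(rates, dict):
            d["rates"] = GrowthRateSpec(**rates)
        return cls(**d)
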