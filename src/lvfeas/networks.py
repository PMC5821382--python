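"""Random and trophically structured ecological network generators.

Seven topology families are supported, in two classes:

* **Unstructured** (Erdős–Rényi): a *directed* variant where every ordered
  pair is linked independently (May's random model), and a *paired* variant
  where unordered pairs are linked in both directions (the substrate for
  mutualistic, competitive and predator-prey communities).
* **Structured predation** (cascade, niche, nested-hierarchy): species carry
  a hierarchy/niche ordering and the predation adjacency is strictly
  triangular under it, so the trophic graph is acyclic by construction.

Conventions: ``alpha[i, j] = 1`` means species *i* receives a direct
per-capita effect from *j*; for predation topologies it means *i* preys on
*j*. The diagonal is always zero — intraspecific regulation is carried by a
separate self-limitation coefficient, never by the adjacency. Connectance is
``C = L / (S*(S-1))`` with ``L`` the number of nonzero entries of ``alpha``;
under that convention the structured generators target a realized
connectance of ``C/2`` while the unstructured ones target ``C``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Topology",
    "TrophicRoles",
    "STRUCTURED_TAGS",
    "PREDATION_TAGS",
    "generate_unstructured",
    "generate_cascade",
    "generate_niche",
    "generate_nested_hierarchy",
    "connectance",
    "trophic_roles",
]

STRUCTURED_TAGS = frozenset({"cascade", "niche", "nested_hierarchy"})
PREDATION_TAGS = STRUCTURED_TAGS | {"unstructured_paired"}
_ALL_TAGS = PREDATION_TAGS | {"may_directed"}


@dataclass(frozen=True)
class Topology:
    """A binary interaction topology.

    Attributes
    ----------
    S : int
        Species count.
    alpha : (S, S) int array
        Binary adjacency, zero diagonal. ``alpha[i, j] = 1``: species *i*
        receives a direct effect from *j* (*i* preys on *j* for trophic
        models). For structured models species are stored in ascending
        hierarchy order: index 0 is the most basal, index S-1 the top.
    model_tag : str
        One of ``may_directed``, ``unstructured_paired``, ``cascade``,
        ``niche``, ``nested_hierarchy``.
    C_target : float
        Nominal connectance parameter handed to the generator.
    """

    S: int
    alpha: np.ndarray
    model_tag: str
    C_target: float

    def __post_init__(self):
        if self.S < 2:
            raise ValueError("S must be >= 2")
        if self.model_tag not in _ALL_TAGS:
            raise ValueError(f"unknown model_tag {self.model_tag!r}")
        a = np.asarray(self.alpha)
        if a.shape != (self.S, self.S):
            raise ValueError("alpha must be S x S")
        if not np.isin(a, (0, 1)).all():
            raise ValueError("alpha must be binary")
        if np.diagonal(a).any():
            raise ValueError("alpha must have a zero diagonal")
        object.__setattr__(self, "alpha", a.astype(np.int8))


@dataclass(frozen=True)
class TrophicRoles:
    """Trophic classification of every species in a predation web.

    ``roles[i]`` is ``"basal"`` (no prey), ``"top"`` (no predators, at least
    one prey) or ``"intermediate"``. ``ranks[i]`` is the normalized hierarchy
    position in [0, 1] with 0 = top of the web and 1 = most basal, matching
    the convention of plotting species from top predator to basal autotroph.
    ``isolated`` flags species with neither prey nor predators (classified
    basal).
    """

    roles: tuple
    ranks: np.ndarray
    isolated: np.ndarray


def _check_params(S, C):
    if not isinstance(S, (int, np.integer)) or S < 2:
        raise ValueError(f"S must be an integer >= 2, got {S!r}")
    if not (0.0 < C < 1.0):
        raise ValueError(f"C must lie in (0, 1), got {C!r}")


def generate_unstructured(S: int, C: float, mode: str = "directed",
                          rng: np.random.Generator | None = None) -> Topology:
    """Erdős–Rényi topology.

    ``mode="directed"`` links every ordered off-diagonal pair independently
    with probability C (May's random model). ``mode="paired"`` links every
    unordered pair with probability C, setting both directions — the
    substrate for mutualism/competition/predation sign structures.
    """
    _check_params(S, C)
    rng = np.random.default_rng(rng)
    if mode == "directed":
        alpha = (rng.random((S, S)) < C).astype(np.int8)
        np.fill_diagonal(alpha, 0)
        return Topology(S, alpha, "may_directed", C)
    if mode == "paired":
        upper = np.triu((rng.random((S, S)) < C).astype(np.int8), k=1)
        alpha = upper + upper.T
        return Topology(S, alpha, "unstructured_paired", C)
    raise ValueError(f"mode must be 'directed' or 'paired', got {mode!r}")


def generate_cascade(S: int, C: float,
                     rng: np.random.Generator | None = None) -> Topology:
    """Cascade food web: species i may prey only on lower-ranked j < i.

    Each of the S(S-1)/2 candidate predator-prey pairs is linked
    independently with probability C, so the realized connectance
    L/(S(S-1)) concentrates around C/2.
    """
    _check_params(S, C)
    rng = np.random.default_rng(rng)
    alpha = np.tril((rng.random((S, S)) < C).astype(np.int8), k=-1)
    return Topology(S, alpha, "cascade", C)


def _niche_adjacency(n, x, u):
    """Adjacency from per-species niche parameters.

    Diet of species i is the contiguous niche interval of half-width
    r_i/2 = x_i*n_i/2 centred at c_i = r_i/2 + u_i*(n_i - r_i), which lies
    inside [0, n_i]: every prey has a strictly smaller niche value, so the
    web is acyclic and (after sorting) strictly lower-triangular. The
    smallest-niche species is forced to an empty diet, guaranteeing a basal
    species.
    """
    r = x * n
    c = r / 2.0 + u * (n - r)
    lo = (c - r / 2.0)[:, None]
    hi = (c + r / 2.0)[:, None]
    nv = n[None, :]
    alpha = ((nv >= lo) & (nv <= hi)).astype(np.int8)
    np.fill_diagonal(alpha, 0)
    alpha[np.argmin(n), :] = 0
    return alpha


def generate_niche(S: int, C: float, rng: np.random.Generator | None = None,
                   ensure_connected: bool = False,
                   max_iter: int = 10_000) -> Topology:
    """Niche model: interval food webs targeting connectance C/2.

    Each species gets a niche value n_i ~ Uniform(0,1) and consumes all
    species whose niche value falls in a contiguous diet interval. The diet
    fraction x ~ Beta(1, 1/C - 1) makes the expected realized connectance
    L/(S(S-1)) equal C/2 (an unbiased calibration). Duplicated niche
    values are redrawn; species are returned sorted by ascending niche
    value (index 0 = most basal, which is forced to an empty diet so a
    basal species always exists).

    With ``ensure_connected=True``, species left without any link are also
    replaced (new niche value and diet) until every species participates,
    the classic replacement rule. Note this conditions the web on full
    connectivity and inflates the realized connectance by a few percent at
    small S; the default leaves isolated species in place, where
    :func:`trophic_roles` flags them.
    """
    _check_params(S, C)
    if C / 2.0 >= 0.5:
        raise ValueError("niche model requires C/2 < 0.5")
    rng = np.random.default_rng(rng)
    beta = 1.0 / C - 1.0

    n = rng.random(S)
    x = rng.beta(1.0, beta, size=S)
    u = rng.random(S)
    for _ in range(max_iter):
        if np.unique(n).size < S:
            # exact ties are astronomically rare but break strict ordering
            _, first = np.unique(n, return_index=True)
            dup = np.setdiff1d(np.arange(S), first)
            n[dup] = rng.random(dup.size)
            continue
        alpha = _niche_adjacency(n, x, u)
        if not ensure_connected:
            break
        isolated = (alpha.sum(axis=0) + alpha.sum(axis=1)) == 0
        if not isolated.any():
            break
        idx = np.flatnonzero(isolated)
        n[idx] = rng.random(idx.size)
        x[idx] = rng.beta(1.0, beta, size=idx.size)
        u[idx] = rng.random(idx.size)
    else:
        raise RuntimeError("niche model failed to connect all species; "
                           "C may be too small for this S")

    order = np.argsort(n)
    alpha = alpha[np.ix_(order, order)]
    return Topology(S, alpha, "niche", C)


def generate_nested_hierarchy(S: int, C: float,
                              rng: np.random.Generator | None = None,
                              prey_counts=None) -> Topology:
    """Nested-hierarchy food web targeting connectance C/2.

    Species get sorted niche values; prey counts follow the niche model's
    Beta-derived diet fraction (k_i ≈ x*n_i*(S-1), stochastically rounded,
    capped at the number of lower-ranked species). Prey are picked
    sequentially: a random lower-ranked species; once a chosen prey already
    has consumers, the consumer joins that prey's consumer group and
    subsequent prey come from the group's pooled diet — the phylogenetic
    "nested" constraint. Exhausted pools fall back to lower-ranked species
    without consumers, then to any remaining lower-ranked species, keeping
    the web acyclic.

    ``prey_counts`` overrides the random per-species prey counts (testing
    hook); entries are still capped at each species' number of lower-ranked
    species.
    """
    _check_params(S, C)
    rng = np.random.default_rng(rng)
    beta = 1.0 / C - 1.0

    n = np.sort(rng.random(S))
    while np.unique(n).size < S:  # pragma: no cover - measure-zero ties
        n = np.sort(rng.random(S))

    if prey_counts is None:
        x = rng.beta(1.0, beta, size=S)
        v = x * n * (S - 1)
        k = np.floor(v).astype(int) + (rng.random(S) < (v - np.floor(v)))
    else:
        k = np.asarray(prey_counts, dtype=int).copy()
        if k.shape != (S,):
            raise ValueError("prey_counts must have length S")
    k = np.minimum(k, np.arange(S))  # species i has only i lower-ranked prey

    alpha = np.zeros((S, S), dtype=np.int8)
    consumers: list[set] = [set() for _ in range(S)]
    for i in range(1, S):
        need = int(k[i])
        if need == 0:
            continue
        prey: set = set()
        pool: set | None = None
        while len(prey) < need:
            if pool is None:
                cands = [j for j in range(i) if j not in prey]
                j = int(rng.choice(cands))
                prey.add(j)
                if consumers[j]:
                    pooled = set()
                    for cons in consumers[j]:
                        pooled |= set(np.flatnonzero(alpha[cons]))
                    pool = {p for p in pooled if p < i}
            else:
                cands = sorted(pool - prey)
                if cands:
                    prey.add(int(rng.choice(cands)))
                    continue
                cands = [j for j in range(i)
                         if j not in prey and not consumers[j]]
                if not cands:
                    cands = [j for j in range(i) if j not in prey]
                prey.add(int(rng.choice(cands)))
        for j in prey:
            alpha[i, j] = 1
            consumers[j].add(i)
    return Topology(S, alpha, "nested_hierarchy", C)


def connectance(t: Topology, unordered: bool = False) -> float:
    """Realized connectance L / (S*(S-1)).

    By default L counts nonzero entries of ``alpha``: paired webs (which
    store both directions of every link) then report their pair-linking
    probability C, and structured predation webs (one stored direction per
    trophic link) report their C/2 target. With ``unordered=True``, L
    counts unordered linked pairs instead.
    """
    a = t.alpha
    if unordered:
        L = np.count_nonzero(a | a.T) / 2.0
    else:
        L = np.count_nonzero(a)
    return float(L) / (t.S * (t.S - 1))


def trophic_roles(t: Topology) -> TrophicRoles:
    """Classify species as basal / intermediate / top and assign ranks.

    Requires a predation topology. Basal species have no prey (empty row of
    ``alpha``); top species have at least one prey and no predators (empty
    column); everything else is intermediate. Isolated species (no links at
    all) classify as basal and are flagged. Rank is the species' normalized
    hierarchy position: 0 for the top of the web, 1 for the most basal.

    For paired (symmetric) predation topologies the predator direction is
    only decided when interaction strengths are sampled, so every linked
    species is intermediate here and ranks follow the storage order.
    """
    if t.model_tag not in PREDATION_TAGS:
        raise ValueError(
            f"trophic roles are defined for predation topologies, "
            f"not {t.model_tag!r}")
    n_prey = t.alpha.sum(axis=1)
    n_pred = t.alpha.sum(axis=0)
    roles = []
    for i in range(t.S):
        if n_prey[i] == 0:
            roles.append("basal")
        elif n_pred[i] == 0:
            roles.append("top")
        else:
            roles.append("intermediate")
    isolated = (n_prey == 0) & (n_pred == 0)
    # species are stored basal-to-top; rank 1 = basal end, 0 = top end
    ranks = 1.0 - np.arange(t.S) / (t.S - 1)
    return TrophicRoles(tuple(roles), ranks, isolated)
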