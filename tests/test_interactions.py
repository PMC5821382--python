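"""Interaction strengths: sign structure, scaling, and moments."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

from lvfeas.config import CommunityConfig
from lvfeas.interactions import (mean_interaction_matrix,
                                 mean_pairwise_strength,
                                 normalization_factor,
                                 sample_interaction_matrix)
from lvfeas.networks import (generate_cascade, generate_niche,
                             generate_unstructured)


@pytest.mark.parametrize("C,S,delta,expected", [
    (0.25, 100, 0.0, 1.0),
    (0.25, 100, 0.5, 0.2),
    (0.4, 150, 1.0, 1.0 / 60.0),
])
def test_normalization_factor_values(C, S, delta, expected):
    assert normalization_factor(C, S, delta) == pytest.approx(expected)


def test_normalization_factor_domain():
    with pytest.raises(ValueError):
        normalization_factor(0.25, 100, 1.5)
    with pytest.raises(ValueError):
        normalization_factor(0.25, 100, -0.1)


@given(st.floats(0.01, 0.99), st.integers(5, 500),
       st.floats(0.0, 0.99), st.floats(0.001, 0.3))
def test_normalization_strictly_decreasing_in_delta(C, S, d1, step):
    """For C*S > 1 the scaling factor strictly decreases with delta."""
    if C * S <= 1.0:
        return
    d2 = min(1.0, d1 + step)
    if d2 > d1:
        assert normalization_factor(C, S, d2) < normalization_factor(C, S, d1)


def test_mutualism_competition_signs(rng):
    t = generate_unstructured(30, 0.3, "paired", rng)
    mu = sample_interaction_matrix(t, "mutualism", 0.4, rng)
    co = sample_interaction_matrix(t, "competition", 0.4, rng)
    support = t.alpha.astype(bool)
    assert (mu.A[support] > 0).all() and (mu.A[~support] == 0).all()
    assert (co.A[support] < 0).all() and (co.A[~support] == 0).all()


@pytest.mark.parametrize("topology", ["paired", "cascade", "niche"])
def test_predation_antisymmetric_signs(topology, rng):
    """Every linked pair satisfies sign(a_ij) = -sign(a_ji)."""
    if topology == "paired":
        t = generate_unstructured(25, 0.3, "paired", rng)
    elif topology == "cascade":
        t = generate_cascade(25, 0.3, rng)
    else:
        t = generate_niche(25, 0.3, rng)
    im = sample_interaction_matrix(t, "predation", 0.4, rng)
    ii, jj = np.nonzero(im.A)
    assert ii.size > 0
    for i, j in zip(ii, jj):
        assert im.A[i, j] * im.A[j, i] < 0
    if topology != "paired":
        # stored direction is the predator side: positive on alpha support
        assert (im.A[t.alpha.astype(bool)] > 0).all()


def test_may_mixture_support_and_moments(rng):
    """Pooled nonzero entries have mean ~0 and sd ~sigma (3-SE bands)."""
    sigma, vals = 0.4, []
    for _ in range(100):
        t = generate_unstructured(40, 0.25, "directed", rng)
        im = sample_interaction_matrix(t, "may_mixture", sigma, rng)
        assert ((im.A != 0) <= t.alpha.astype(bool)).all()
        vals.append(im.A[t.alpha.astype(bool)])
    v = np.concatenate(vals)
    assert abs(v.mean()) < 3 * sigma / np.sqrt(v.size)
    # SE of the sd of a Gaussian sample: sigma / sqrt(2 n)
    assert abs(v.std(ddof=1) - sigma) < 3 * sigma / np.sqrt(2 * v.size)


def test_folded_gaussian_magnitude_moments(rng):
    """|N(0, sigma)| entries have mean sigma*sqrt(2/pi) and variance
    sigma^2*(1 - 2/pi)."""
    sigma = 0.4
    t = generate_unstructured(60, 0.4, "paired", rng)
    vals = np.concatenate([
        sample_interaction_matrix(t, "mutualism", sigma, rng).A[
            t.alpha.astype(bool)] for _ in range(50)])
    m_th = sigma * math.sqrt(2 / math.pi)
    v_th = sigma ** 2 * (1 - 2 / math.pi)
    assert abs(vals.mean() - m_th) < 3 * np.sqrt(v_th / vals.size)
    assert abs(vals.var(ddof=1) - v_th) < 0.05 * v_th


def test_incompatible_type_topology_pairs(rng):
    t_dir = generate_unstructured(10, 0.3, "directed", rng)
    t_str = generate_cascade(10, 0.3, rng)
    with pytest.raises(ValueError):
        sample_interaction_matrix(t_dir, "predation", 0.4, rng)
    with pytest.raises(ValueError):
        sample_interaction_matrix(t_str, "may_mixture", 0.4, rng)
    with pytest.raises(ValueError):
        sample_interaction_matrix(t_str, "mutualism", 0.4, rng)


def test_identical_seed_identical_matrix():
    t = generate_cascade(15, 0.3, np.random.default_rng(3))
    A1 = sample_interaction_matrix(t, "predation", 0.4,
                                   np.random.default_rng(9)).A
    A2 = sample_interaction_matrix(t, "predation", 0.4,
                                   np.random.default_rng(9)).A
    np.testing.assert_array_equal(A1, A2)


def test_mean_pairwise_strength_closed_forms():
    m = 0.4 * math.sqrt(2 / math.pi)
    assert mean_pairwise_strength("may_mixture", 0.4) == 0.0
    assert mean_pairwise_strength("predation", 0.4) == 0.0
    assert mean_pairwise_strength("mutualism", 0.4) == pytest.approx(m)
    assert mean_pairwise_strength("competition", 0.4) == pytest.approx(-m)


def test_mean_interaction_matrix_closed_forms():
    cfg = CommunityConfig(S=6, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                          model="may")
    np.testing.assert_array_equal(mean_interaction_matrix(cfg),
                                  np.zeros((6, 6)))
    cfg = CommunityConfig(S=6, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                          model="mutualism")
    A_bar = mean_interaction_matrix(cfg)
    off = A_bar[~np.eye(6, dtype=bool)]
    assert off == pytest.approx(0.25 * 0.4 * math.sqrt(2 / math.pi))
    assert np.diagonal(A_bar).sum() == 0.0


def test_mean_interaction_matrix_mc_agrees_with_closed_form(rng):
    """Monte-Carlo averaging converges to the folded-normal closed form."""
    cfg = CommunityConfig(S=10, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                          model="mutualism")
    closed = mean_interaction_matrix(cfg)
    mc = mean_interaction_matrix(cfg, M=3000, rng=rng, method="mc")
    off = ~np.eye(10, dtype=bool)
    # SE of the pooled off-diagonal mean over M draws and 90 entries
    per_entry_var = 0.25 * 0.4 ** 2  # Bernoulli(C) x folded-normal, approx
    se = np.sqrt(per_entry_var / (3000 * off.sum()))
    assert abs(mc[off].mean() - closed[off].mean()) < 3 * se


def test_mean_interaction_matrix_structured_mc_is_antisymmetric_in_sign(rng):
    """For trophic webs the mean matrix is positive above the hierarchy
    direction and negative on the transpose side."""
    cfg = CommunityConfig(S=8, C=0.4, delta=0.5, theta=-1.0, sigma=0.4,
                          model="cascade")
    A_bar = mean_interaction_matrix(cfg, M=400, rng=rng)
    assert (np.tril(A_bar, -1) >= 0).all()
    assert (np.triu(A_bar, 1) <= 0).all()
    assert np.tril(A_bar, -1).max() > 0
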