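# Methods

## Model

The package studies generalized Lotka–Volterra dynamics on `S` species,

```
dx_i/dt = x_i ( r_i + θ x_i + f Σ_j a_ij x_j ),    f = (CS)^(−δ),
```

where `r_i` are intrinsic growth rates, `θ < 0` is uniform
self-regulation, `A = (a_ij)` is the interaction matrix with zero
diagonal, `C` is the connectance, and `δ ∈ [0, 1]` normalizes
interaction strength by the expected number of links per species. The
unique interior equilibrium solves the linear system

```
(θI + fA) x* = −r,
```

and is *feasible* when every component is strictly positive. The
feasibility probability `P_S` is the probability of this event over the
random draw of the web and the interaction strengths. Local stability
of a feasible equilibrium is governed by the community Jacobian
`J = diag(x*)(θI + fA)`; the equilibrium is stable when the leading
eigenvalue real part is strictly negative.

Three scaling regimes follow from `f`:

- **strong** (`0 ≤ δ < 1/2`): total interaction input grows with `S`;
  May's criterion `σ (CS)^(1/2−δ) < |θ|` eventually fails and both
  stability and feasibility are lost as `S` grows;
- **moderate** (`δ = 1/2`): the criterion reduces to `σ < |θ|`,
  independent of `S` and `C`; feasibility decays geometrically in `S`;
- **weak** (`1/2 < δ ≤ 1`): interactions vanish relative to
  self-regulation and feasibility is asymptotically determined by the
  mean structure alone.

The regime boundary is an exact comparison: `δ = 0.5` classifies as
moderate, any other float as strong or weak. Since the three regimes
have qualitatively different asymptotics, no tolerance band around 1/2
would be principled.

## Growth rates and the structural vector

Unless configured otherwise, experiments use the *mean structural
vector*

```
r = −(θI + f Ā) · 1,
```

where `Ā` is the mean interaction matrix. This choice places the
equilibrium of the mean-field system exactly at the all-ones abundance
vector, so any infeasibility observed is attributable to interaction
disorder, not to a biased choice of rates. `Ā` has a closed form for
unstructured models (zero off-diagonal mean for the random-mixture and
symmetric predator–prey cases; `±C σ √(2/π)` for mutualism and
competition) and is estimated by averaging `M = 200` sampled webs for
the structured food-web models.

Under weak scaling (`δ = 1`) the per-link factor `f = (CS)^(−1)` keeps
structural row sums within `± σ √(2/π)` of zero, so all structural
rates stay positive. Under moderate scaling the trophic asymmetry of
structured webs is not normalized away, and top consumers acquire
negative structural growth rates at realistic sizes (e.g. the niche
model at `S = 100`, `C = 0.25` spans roughly `r ∈ [−0.7, 2.3]`) — the
obligate-consumer signature.

Alternative rate specifications: i.i.d. Gaussian, i.i.d. uniform, and
fixed user-supplied vectors.

## Closed-form theory

For the moderate regime with unstructured interactions, zero-mean
disorder, and the structural vector, the feasibility probability is
approximated by treating the equilibrium abundances as asymptotically
independent Gaussians:

```
P_S ≈ Φ( √((θ² − σ²)/σ²) )^S,        0 < σ < |θ|,
```

computed in log space (`exp(S · logcdf)`) to avoid underflow at large
`S`. The matching abundance moments for mean rate `r̄` and rate
variance `σ_r²` are

```
μ* = −r̄/θ,
σ*² = σ_r²/θ² + ⟨r²⟩ σ² / (θ²(θ² − σ²)),    ⟨r²⟩ = σ_r² + r̄².
```

In the weak regime, `P_S → 1` exactly when
`min_i r_i > r̄ μ_A / (μ_A + θ)` with `μ_A` the mean pairwise
interaction (`0` for the random mixture and symmetric predator–prey,
`± σ √(2/π)` for mutualism/competition), and `P_S → 0` otherwise.

### Finite-size accuracy of the closed form

The `Φ^S` formula is an asymptotic statement; at finite `S` the exact
abundances are weakly coupled and the formula overestimates `P_S`. With
`C = 0.25`, `σ = 0.4`, `θ = −1`, independent Monte-Carlo runs (10⁴–10⁵
replicates, including a from-scratch implementation outside this
package) put the gap at about −0.022, −0.031, and −0.034 at
`S = 10, 25, 50`, i.e. roughly 2.2–2.3 times the half-width of a 95%
binomial envelope around the prediction at 1000 replicates. The
end-to-end check that compares the two at that envelope therefore fails
at `S = 50`; this is a property of the approximation, not of the
estimator, and the test is kept strict rather than widened.

## Network generators

All generators share one connectance convention — `C = L/(S(S−1))` with
`L` the number of nonzero entries of the adjacency matrix — and store
species in ascending hierarchy order (index 0 basal) with normalized
rank `1 − i/(S−1)`.

- **Unstructured (directed / paired)**: each ordered link (or unordered
  pair, both directions) present independently with probability `C`.
- **Cascade**: each ordered pair `(i, j)` with `j` below `i` in the
  hierarchy linked independently with probability `C`; realized
  connectance `C/2` on the directed convention.
- **Niche**: niche values `x_i ~ U(0,1)`, diet breadth
  `n_i = x_i · B` with `B ~ Beta(1, 1/C − 1)`, and a diet interval of
  width `n_i` centred at `c_i = n_i/2 + u (x_i − n_i/2)`, `u ~ U(0,1)`,
  which keeps the interval inside `[0, x_i]` and hence the web acyclic
  with exactly interval diets. Webs where two species draw effectively
  identical niche positions are redrawn. By default no connectivity
  repair is applied — rejection or redraw conditioning measurably
  inflates realized connectance (≈ +5% relative at `S = 30`,
  `C = 0.25`), so the default generator is calibrated to hit `C/2`
  unbiasedly and isolated species are simply flagged by the
  trophic-role classifier; `ensure_connected=True` enables
  isolated-species replacement when a connected web is required.
- **Nested hierarchy**: species sorted by niche value; consumer `i`
  receives `k_i` prey, a stochastic rounding of `x_i · B · (S−1)`
  capped at the number of lower-ranked species (preserving acyclicity;
  the cap biases realized connectance by ≈ −1.3% relative, within the
  calibration tolerance). Prey are chosen sequentially: a random
  lower-ranked species first, then, when the chosen prey already has
  consumers, the remaining prey are drawn from the pooled diets of that
  prey's consumer group before falling back to unconsumed lower-ranked
  species.

A calibration test checks each structured generator's mean realized
connectance against `C/2` within three standard errors over 1000 draws.

## Numerical choices

- **Linear solve**: LAPACK LU factorization (`scipy` `lu_factor` /
  `lu_solve`) with a 1-norm condition estimate (`gecon`). Draws with
  condition estimate above `10¹²` are flagged *degenerate* and excluded
  from both numerator and denominator of `P_S` (counted separately and
  warned about above 5%); near-singular draws would otherwise
  contribute sign patterns dominated by rounding error.
- **Residual guard**: accepted solves must satisfy
  `‖Bx* + r‖_∞ < 10⁻⁹ · scale`.
- **Feasibility**: strict `x*_i > 0`; an exact zero is infeasible.
- **Stability**: dense nonsymmetric eigensolve (`numpy.linalg.eigvals`)
  with a strict `Re λ < 0` test — no tolerance, since the Jacobian of a
  feasible generic draw has eigenvalues bounded away from zero.
- **Confidence intervals**: Wilson score intervals
  (`statsmodels.stats.proportion.proportion_confint`) at 95%, which
  behave correctly at `p̂ ∈ {0, 1}` where the Wald interval collapses.
- **Seeding**: all randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (`SeedSequence([base, S, rep])`
  per replicate; string keys hashed via CRC-32), so experiments are
  reproducible and replicates are statistically independent streams.
- **ODE cross-check**: `scipy.integrate.solve_ivp` at
  `rtol = atol = 10⁻¹⁰` over `t ∈ [0, 600]` from a 5%-perturbed start
  must return to the linear-solve equilibrium within `10⁻⁶` sup-norm
  for small stable feasible systems.

## Problem sizes exercised

The test suite and acceptance script run Monte-Carlo experiments up to
`S = 1000` (single solve per replicate, ~100 replicates), feasibility
envelopes at `S = 10–50` with 1000 replicates, abundance summaries at
`S = 200–400` with 300–500 replicates, and generator calibrations with
1000 draws at `S = 30`. The full suite completes in well under a minute
on a laptop-class machine.

## Limitations

- The moderate-regime closed form carries the finite-size bias
  quantified above; it should be read as an asymptotic envelope, not a
  finite-`S` prediction.
- The weak-regime limit is a 0/1 law about the `S → ∞` mean-field
  system; at finite `S` it describes the direction of convergence only.
- Structured-model mean matrices are Monte-Carlo estimates (`M = 200`
  by default), so structural vectors for those models carry `O(M^{-1/2})`
  sampling noise.
- Degenerate-draw exclusion conditions `P_S` on well-posedness; at the
  parameter ranges exercised here degenerate draws are rare (0 in the
  documented runs), but the conditioning matters near `σ → |θ|`.
- The stability analysis is local (linearization at the interior
  equilibrium); no claims are made about global dynamics or boundary
  attractors.
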