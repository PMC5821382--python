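# lvfeas — feasibility of large Lotka–Volterra communities

`lvfeas` is a small research package for studying when large ecological
communities admit a *feasible* equilibrium — one with every species at
positive abundance — under generalized Lotka–Volterra dynamics

```
dx_i/dt = x_i ( r_i + θ x_i + (CS)^(−δ) Σ_j a_ij x_j )
```

with `S` species, connectance `C`, self-regulation `θ < 0`, interaction
strengths `a_ij` of scale `σ`, and a normalization exponent `δ ∈ [0, 1]`
that sets how interaction strength scales with the expected number of
links per species. The equilibrium is the solution of a linear system,
`x* = −(θI + (CS)^(−δ)A)^(−1) r`, and its local stability is read off
the community Jacobian `J = diag(x*)(θI + (CS)^(−δ)A)`.

The package implements the full pipeline:

- **Network generators** (`lvfeas.networks`) — unstructured directed and
  paired Erdős–Rényi webs, and three trophically structured food-web
  models: cascade, niche, and nested-hierarchy. All produce acyclic
  (hierarchy-ordered) webs with a common connectance convention
  `C = L / (S(S−1))`.
- **Interaction sampling** (`lvfeas.interactions`) — random-mixture
  (May-style), mutualistic, competitive, and predator–prey sign
  structures with half-normal magnitudes of scale `σ`, plus closed-form
  or Monte-Carlo mean interaction matrices.
- **Equilibrium core** (`lvfeas.equilibrium`) — LU solves with a
  condition-number guard, feasibility tests, Jacobians, and the raw
  Lotka–Volterra vector field for ODE cross-checks.
- **Theory** (`lvfeas.theory`) — regime classification (strong
  `δ < 1/2`, moderate `δ = 1/2`, weak `δ > 1/2`), May's stability
  criterion `σ (CS)^(1/2−δ) < |θ|`, the moderate-regime closed form
  `P_S ≈ Φ(√((θ²−σ²)/σ²))^S` with the matching abundance moments, and
  the weak-interaction feasibility limit.
- **Experiments** (`lvfeas.experiments`) — seeded Monte-Carlo estimation
  of the feasibility probability `P_S` with Wilson confidence intervals,
  feasibility curves over `S`, trophic-role abundance summaries, and
  stability-given-feasibility reports.
- **I/O and CLI** (`lvfeas.io`, `lvfeas.cli`) — edge-list topology
  files, validated YAML experiment configs, JSON run manifests with
  checksums, and a `lvfeas` command-line interface.

## Worked example

Estimate the feasibility probability of a moderate-regime (`δ = 1/2`)
unstructured community and compare it with the closed form:

```python
from lvfeas import (CommunityConfig, estimate_feasibility,
                    analytic_feasibility_probability)

cfg = CommunityConfig(S=50, C=0.25, delta=0.5, theta=-1.0, sigma=0.4,
                      model="may", seed=42)
est = estimate_feasibility(cfg, n_reps=500)
print(f"P_S estimate: {est.p_hat:.3f} "
      f"(95% CI {est.ci_low:.3f}-{est.ci_high:.3f}, n={est.n_total})")
print(f"closed form:  {analytic_feasibility_probability(50, 0.4, -1.0):.3f}")
```

prints

```
P_S estimate: 0.556  (95% CI 0.512-0.599, n=500)
closed form:  0.576
```

(The closed form is asymptotic in `S`; at finite `S` the Monte-Carlo
estimate runs slightly below it — see `docs/methods.md`.)

Structured webs show a characteristic trophic ordering of abundance
variability — basal species are the most predictable, top predators the
least:

```python
from lvfeas import abundance_summary

niche = CommunityConfig(S=100, C=0.25, delta=1.0, theta=-1.0, sigma=0.4,
                        model="niche", seed=42)
summ = abundance_summary(niche, 200)
for role, sd in summ.role_sd.items():
    print(f"sd[{role}] = {sd:.3f}")
```

```
sd[basal] = 0.068
sd[intermediate] = 0.141
sd[top] = 0.236
```

The same experiment from the command line, driven by a YAML config:

```
$ cat demo.yml
model: may
S: 50
C: 0.25
sigma: 0.4
theta: -1
delta: "0.5"
seed: 42
$ lvfeas feasibility --config demo.yml --reps 500 --out-dir demo_out
P_S = 0.5560 [0.5122, 0.5990] (278/500 feasible, 0 degenerate)
```

Other subcommands: `lvfeas generate` (write a topology edge list),
`lvfeas curve` (Monte-Carlo `P_S` over a list of `S` values, with the
closed-form prediction where it applies), `lvfeas abundances`
(per-species abundance summary with trophic roles), and `lvfeas theory`
(regime and stability-criterion table over `S`). Every run directory
gets a `manifest.json` recording the config, seed, package version, and
SHA-256 checksums of the outputs, so runs are reproducible and
verifiable.

## Testing

```
python -m pytest -q tests/
```

The suite covers the generators (triangularity, intervality,
connectance calibration), hand-solved equilibria, an ODE integration
oracle against the linear solve, the closed-form/Monte-Carlo agreement,
Gaussian abundance marginals, feasibility-implies-stability, and the
I/O and CLI surface. `tests/test_acceptance.py` holds the end-to-end
scientific checks; the remaining files are unit and property tests.

One known limitation is exercised deliberately: the moderate-regime
closed form `Φ(·)^S` overestimates the finite-`S` feasibility
probability by a few percent (the Monte-Carlo estimate at `S = 50`
falls outside a 95% binomial envelope around it), so the corresponding
end-to-end check fails at `S = 50` by design. See
`docs/methods.md` for the quantitative analysis.
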