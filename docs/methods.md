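# Methods

## Model

A pathway is a set of species `j` with activations `x_j ∈ [0, 1]` and gated
reactions `i`, each with reactant set `R_i` (activating inputs), inhibitor
set `I_i` (inputs entering as their complement), and product set `P_i`. The
cardinality invariant `|R_i| + |I_i| ∈ {1, 2}` restricts every gate to at
most two inputs; larger logic is expressed by composing reactions. OR
semantics are implicit: all reactions sharing a product are combined.

**Transfer function.** Each reaction transmits its gate input `u` through a
normalized Hill function

```
f(u) = a · H(u) / H(1),    H(u) = u^n / (p^n + u^n)
```

so `f(0) = 0` and `f(1) = a`. The gain `a ∈ [0, 1]` caps the transmitted
signal — `a ≈ 0` removes the reaction — and the midpoint `p` sets where the
curve turns on. The Hill coefficient `n` is a positive integer shared by all
reactions and held fixed at 4 during fitting, so each reaction contributes
exactly two free parameters.

**Gates.** The gate input of reaction `i` is the bilinear product
`u_i = Π_{j∈R_i} x_j · Π_{j∈I_i} (1 − x_j)`; the reaction activity is
`z_i = f(u_i)`. A species produced by reactions `T_j` takes the
probabilistic sum `x_j = 1 − Π_{i∈T_j} (1 − z_i)`, computed recursively as
`u_m = u_{m−1} + z_m − u_{m−1} z_m`. At binary inputs these reduce exactly
to Boolean AND/AND-NOT and OR, which the test suite verifies against an
independent truth-propagation oracle on 200 random networks.

**Steady state.** Each experiment clamps its applied stimuli and inhibitor
nodes to 1 and all other treatment-capable nodes to 0. Acyclic networks are
evaluated in a single topological pass (edges into clamped species are cut,
so clamps break cycles through them). Cyclic networks are iterated
synchronously from the all-zero state until the largest activation change
falls below 1e-9 (at most 100 iterations); non-convergent oscillations raise
an error naming the cycle.

## Training problem

Given measurements `x̂_j^k` for signal `j` under experiment `k`, training
minimizes

```
Σ_k Σ_j α_j^k · ρ(x_j^k − x̂_j^k)
```

over all gains and midpoints, with per-cell weights `α` (default 1). The
mismatch kernel is the smoothed absolute value `ρ(r) = sqrt(r² + ε)` with
`ε = 1e-8`, so the optimized objective shares its shape with the reported
mean absolute error (MAE) while staying differentiable; a squared kernel is
available behind the `loss="squared"` flag. The reported goodness-of-fit
metric is always the plain MAE over measured cells.

The formulation is reduced-space: activations are computed by simulation
inside the objective rather than carried as constrained variables, so any
bounded gradient-based local solver applies. The backend is scipy's
L-BFGS-B with forward finite-difference gradients (step 1e-6), bounds
`a ∈ [0, 1]` and `p ∈ [p_lb, p_ub]`.

**Midpoint bounds.** The default search space is `p ∈ [0.1, 0.4375]`; the
toy preset uses `p ∈ [0.3, 0.7]`, bracketing the data-generating midpoint
0.5 between an over-responsive (0.3) and an under-responsive (0.7) curve.
`select_bounds` fits once per candidate pair on a user grid and returns the
MAE-minimizing pair, ties broken toward the narrower interval.

**Saddle-escape polish.** With `n > 1` the transfer function has zero slope
at zero input, so a gain parked near its lower bound can sit at a flat
stationary point even when raising it strictly improves the fit (the
finite-difference gradient vanishes there). After the main solve, each gain
within 1e-2 of its lower bound is probe-lifted in turn: it is clamped to a
probe magnitude (0.5, then 1.0, then 0.1) while the remaining parameters
re-converge, then released for a final free solve. The lifted solution is
kept only if it strictly improves the objective; rejected (gain, magnitude)
probes are not retried, at most 3 polish rounds run, and an already-exact
fit skips polishing. A solution is never allowed to end above its starting
objective. On the toy problem this polish removes all multistart outliers:
400 random restarts across 8 seeds all reach the global optimum.

**Multistart.** Run `r` of a family draws its uniform-random initial guess
from an independent stream seeded by `(seed, r)`, so families are
reproducible and a longer family extends a shorter one. Family statistics
report the MAE spread, the per-reaction average maximum activity across
runs, and the fraction of runs in which each gain ended below 0.05
(candidate eliminations).

## Network reduction

**Compartmentalization.** The network is simulated with nominal parameters
(`a = 1, p = 0.5, n = 4`) under every experimental condition; since clamps
are binary, this is the Boolean regime and responses are exactly 0/1.
Latent species that are neither measured nor used as treatments and whose
response vectors agree (tolerance 1e-9) are merged into one compartment
node; rewritten reactions falling entirely inside a compartment are dropped
and flagged *not interrogated*, and duplicate rewritten reactions are merged
keeping the smallest original id. Measured-node predictions under nominal
parameters are invariant under this reduction (verified to 1e-9 on random
fixtures). Grouping can be over-aggressive when conditions are few — species
the data could distinguish may still respond identically under the executed
conditions — so `compartmentalization_report` warns when the post-fit MAE
exceeds a threshold (default 0.1), and `map_back` projects a
compartment-level solution onto the original network.

**Pruning.** Starting from a multistart baseline fit, the reaction with the
smallest maximum activity `max_k z_i^k` (ties: smallest id) is removed and
the model refit with a small multistart (default 5 restarts, guarding
against a local minimum mimicking an MAE increase). Removal stops — and the
last removal is restored — once the refit MAE exceeds the baseline by more
than a tolerance (default 0.01). The null solution (all gains zero) gives
the ceiling error `mean |x̂|`, 0.311 on the toy data.

## Cross-validation

For each exclusion fraction and replicate, a random subset of measured
cells (default) or whole conditions (`mode="condition"`) is removed from
training; the refit model is scored on all cells and on the held-out cells.
Replicate streams are seeded by `(seed, fraction-index, replicate)`. On the
toy data the total error rises from 0 toward the null ceiling as the
fraction approaches 0.95, while the held-out error stays near zero at small
fractions. Occasionally a replicate at a small fraction excludes exactly
the cells that identify a parameter; the refit then matches the training
cells perfectly but mispredicts the held-out ones. This is genuine
non-identifiability under data removal, not an optimizer failure, and it is
why the evaluation reports replicate averages.

## Synthetic generator

`make_toy_ground_truth` builds the fixed ten-reaction toy study: 2 stimuli,
2 explicit small-molecule inhibitor nodes (represented in the network with
NOT inputs), 1 latent kinase, 5 measured phosphoproteins; a 3 × 3
combinatorial design (9 experiments, 45 cells); active reactions at
`a = 1, p = 0.5` and three reactions disabled (`a = 0`). `random_pathway`
generates random acyclic logic networks: species in a topological layout
with stimuli first, one activating backbone reaction per non-stimulus
species guaranteeing reachability, plus random extra gates with configurable
AND and NOT fractions; sinks become measured nodes. `inject_cycle=True`
adds a back-edge (plus its forward complement when missing) guaranteeing a
directed cycle. `generate_dataset` adds optional truncated-Gaussian noise
(clipped to [0, 1]).

Scope limits: the generator produces single-product reactions only (the SIF
dialect cannot express multi-product reactions), designs are explicit
treatment lists or full binary enumerations, and noise is i.i.d. per cell.

## Numerical choices and limitations

- Hill coefficient fixed at `n = 4`; fitting `n` is out of scope.
- Fixed-point tolerance 1e-9, max 100 iterations; compartment response
  tolerance 1e-9 (responses are exactly 0/1 there, so the tolerance only
  guards floating-point noise).
- Finite-difference gradients make each objective gradient cost
  `2 · n_reactions + 1` simulations; problem sizes exercised here (up to
  228 reactions structurally, 10 reactions for full fits) keep runtimes in
  seconds to minutes. Larger fits would benefit from analytic gradients,
  which are not implemented.
- L-BFGS-B is a local solver; global optimality is approached only through
  multistart plus the saddle polish, and the spread of the resulting family
  is part of the reported output rather than a hidden assumption.
- The smoothed-absolute objective is non-convex through the simulation;
  tolerances quoted above were chosen a priori and are exercised, not tuned,
  by the test suite.
- Cross-validation refits with a single random start per replicate for
  cost; rare replicate-level outliers are averaged, as discussed above.
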