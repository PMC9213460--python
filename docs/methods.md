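# Methods

## Model

The environment is an infinitely deep, infinitely wide rooted tree.
Sampling a node reveals its expected reward: `R+ = +1` with probability
`p`, `R- = -p/(1-p)` with probability `1-p`, i.i.d. across nodes;
unsampled nodes keep expected reward 0. The zero-average constraint
`p·R+ + (1-p)·R- = 0` makes the pre-sampling expectation of every node
zero, so a uniformly random path has expected cumulative reward zero
and any positive policy value is attributable to the information bought
with samples. Allocation is one-shot: all `C` samples are committed
before any outcome is seen, after which the agent follows the path with
the highest expected cumulative reward (backward induction over the
finite sampled sub-tree; the path may traverse unsampled, zero-reward
nodes).

The capacity constraint is enforced *on average*: each node of forward
level `l` receives a sample independently with probability
`q_{d-l+1}` (backward index: `q_1` is the deepest level) and
`Σ_l q_{d-l+1}·b^l = C`. Hard (exactly-`C`) allocation is out of scope.

## Exact engine

Cumulative rewards of the rational reward families live on an integer
lattice: `k = i - n·j` for rich models (`p = n/(n+1)`, `R- = -n`),
and `n·k = n·i - j` for poor models (`p = 1/(n+1)`, `R- = -1/n`).
Distributions are dense float arrays over consecutive integer keys with
an explicit offset; the lattice denominator (`scale`) is 1 (rich) or
`n` (poor). Dense storage matches the linear state count
`N(n, s) = (n+1)s - n(n-1)/2 + 1` (for `s ≥ n`) and keeps the
diffusion step a three-term banded stencil.

Numerical choices:

* `p`, `R-`, capacities and derived `q` are exact `Fraction`s
  throughout the model and allocation layers; floats enter only when a
  distribution array is built.
* Every maximization renormalizes the distribution to unit mass (the
  drift is at the 1e-16 level per step; renormalization at every depth
  rather than only past depth 50 costs one vector division and keeps
  deep recursions well-scaled). Emitted distributions sum to 1 within
  1e-12.
* `b = 1` maximization short-circuits to an exact identity instead of
  the CDF round-trip, and expectations use exactly-rounded summation
  (`math.fsum`); together these make the `b = 1` zero-value identity
  hold exactly in floating point at any depth.
* CDF powers use integer exponents (`b` is an integer branching
  factor); tiny negative masses from cancellation are clipped to zero
  before renormalization.
* Discounting is implemented as per-level survival: with probability
  `1-γ` the continuation is lost and only the immediate reward
  contributes. The recursion applies the survival coin independently
  inside each branch of the maximization; the package does not assert
  the equivalence of this semantics with deterministic exponential
  weighting `γ^l`, and the Monte-Carlo oracle mirrors the coin
  semantics so both routes compute the same quantity.
* Discounted two-branching-factor policies are rejected: discounting is
  analysed for single-`b` homogeneous families only.

A batched variant of the recursion evaluates many heterogeneous `q`
vectors (shared `b`, depth and `γ`) on one `(m × keys)` matrix; it is
what makes finite-difference gradients affordable, and a test pins it
to the scalar path.

## Capacity arithmetic

`derive_homogeneous(b, C)` stacks full levels while their cumulative
cost stays strictly below `C`, then spreads the residual `C_r` over the
`b^{d'}` nodes of the last level (`q_1' = C_r/b^{d'} ∈ (0, 1]`). When
`C` exactly fills `m` levels the result is `d' = m`, `q_1' = 1` — the
residual stays positive and no vacuous extra level is added. The two-`b`
variant spends `Σ_{l≤d1} b1^l` first and continues with levels of
`b1^{d1}·b2^l` nodes; the deep-level multiplier is `b1^{d1}` (the number
of nodes where the second regime starts). If `C` is exhausted inside
the `b1` regime the derivation truncates there (`d2' = 0`), which is
also how the single-`b` family embeds into the two-`b` one. All
derivations are exact rational identities: `capacity_of(policy) == C`,
not merely within tolerance.

The random baseline allocates one uniform probability
`q = C / Σ_{l≤d} b^l` to every node of a tree capped at depth
`d = 2⌊ln C / ln b⌋ + 3` — the same cap used as the default search
depth for heterogeneous policies, deep enough that the optimizer can
spread samples well beyond the homogeneous depth. A uniform `q > 1`
(capacity exceeding the capped tree) is an error.

## Optimizers

*Homogeneous*: scan `b` over a finite grid (default 1..20), deriving
depth and `q_1'` from `C` for each `b`. Ties break toward the smaller
`b` (the deeper policy). The same routine handles the discounted case
at fixed `γ`.

*Two-`b`*: exhaustive grid over `(b1, b2, d1)` with lexicographic
tie-breaking. Grid cells whose capacity is exhausted inside the `b1`
regime collapse to single-`b` policies, so the single-`b` optimum is
always contained in the search space.

*Heterogeneous*: projected gradient ascent on `q` at fixed `b`.
Defaults follow the ascent protocol: forward finite differences with
step `Δq = 1e-7` (central differences optional; components within `Δq`
of the box bound use a backward difference so evaluated vectors stay in
`[0, 1]`), learning rate `η = 1e-3`, up to 1e6 iterations, stop when
the value improves by less than 1e-9. The gradient is projected onto
the hyperplane `Σ q_l·b^l = C`; after the step, feasibility is restored
by clipping to `[0, 1]` and re-projecting. Because that alternating
loop can stall when the iterate is far from the feasible set (it is
capped at `10·d` rounds), the projection falls back to the exact KKT
form `q = clip(q0 + θ·w, 0, 1)` with `θ` found by bisection — the true
Euclidean projection onto the box-hyperplane intersection. An error is
raised only when the intersection is empty (`C` outside
`[0, Σ b^l]`). The value trajectory is nondecreasing by construction
(a step that fails to improve ends the ascent). The ascent is run per
`b`; joint `(b, q)` optimization is a loop over the `b` grid. The
protocol is insensitive to order-of-magnitude changes in the rate: the
initialization-robustness test uses `η = 1e-2` so three different
starts converge within its iteration budget and agree to 1e-4.

Concavity of the value in `q` is observed numerically but not assumed:
no test asserts global optimality of the ascent.

## Analytics

The success probability `P(J_d = d)` (best path all-high) obeys
`P_1 = 1-(1-p)^b`, `P_d = 1-(1-p·P_{d-1})^b`. Its large-depth fixed
point solves `1-P = (1-p·P)^b`; the slope condition at the origin shows
a nonzero root exists iff `p·b > 1`, so the threshold is checked first
and the nontrivial root is found by bracketed `brentq` on
`[1e-15, 1]`. The relative loss of a policy against the optimum is
`100·(V_opt - V)/V_opt`, defined for `V_opt > 0`.

## Oracles and what passing tests show

`enumerate_tree_value` recomputes the expectation in exact rational
arithmetic by walking the sampled sub-tree bottom-up and, at each
level, enumerating all `support^branching` joint child outcomes to take
the maximum explicitly — no CDF powers, no dense lattice, no floats.
It is capped at 64 node slots. The Bellman–Monte-Carlo estimator
instantiates full reward realizations (and survival coins when
`γ < 1`), runs backward induction per realization, and averages;
per-node sampling flags are redrawn on every run, matching the
average-capacity ensemble. Agreement of the engine with enumeration to
1e-12 on random exhaustive/selective/two-`b`/discounted fixtures, and
with Monte Carlo to 4 standard errors at 1e4 runs, is the package's
core correctness evidence.

These checks exercise the model's own assumptions — i.i.d. binary
rewards, level-wise independent Bernoulli sampling, one-shot
allocation. They say nothing about environments with correlated
rewards, feedback-driven (sequential) allocation, or non-binary reward
distributions, all of which are out of scope.

## Problem sizes

Tests and the acceptance script run at the scale the optimizers need:
branching grids to `b = 20`, capacities to 1000 (depths to ~1000 for
`b = 1`), two-`b` grids of 10×10×10 cells, heterogeneous ascents capped
at 1e4 iterations, 50+ oracle fixtures with 1e4 Monte-Carlo runs each.
Full-resolution Monte-Carlo surfaces (millions of repetitions per grid
cell) are intentionally not reproduced; the same quantities are covered
at reduced replication by the statistical gates above.

## Known limitations

* The exact engine requires rational `p`; arbitrary `p` is served only
  by the Monte-Carlo estimator, and `nearest_rational` reports (never
  silently applies) the closest rational model.
* The heterogeneous ascent inherits the usual caveats of local search;
  with the default rate it can need more than 1e4 iterations to reach
  its fixed point at high capacity.
* Values of very deep discounted trees are dominated by the first
  `~1/(1-γ)` levels; the engine is exact there, but optimizing depth
  caps beyond that horizon is wasted effort.
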