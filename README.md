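# treeplan

Finite-capacity sample allocation in infinitely large decision trees.

## The problem

An agent plans over a decision tree that is infinitely deep and
infinitely wide: every node has unboundedly many children, and visiting
a node yields an expected reward that is unknown until the node is
*sampled* (mentally simulated). The agent has a finite budget of `C`
samples to spend in one shot — before any outcome is observed — and
then commits to the path with the highest expected cumulative reward.
The question is the breadth–depth dilemma: should the budget be spread
over many branches per level (breadth) or over few branches across many
levels (depth)?

Sampling a node reveals a high expected reward `R+ = +1` with
probability `p` or a low reward `R- = -p/(1-p)` with probability
`1-p`; unsampled nodes keep expected reward 0. The magnitudes satisfy
the zero-average constraint `p·R+ + (1-p)·R- = 0`, so sampling carries
information but no free reward. `p` measures the richness of the
environment; the exact engine covers the rational families
`p = n/(n+1)` (rich) and `p = 1/(n+1)` (poor).

## The algorithm

The value of an allocation policy is `V = E(J_d)`, the expected
cumulative reward of the best path through the sampled sub-tree.
Rather than enumerating the `3^(#nodes)` joint sampling outcomes,
`treeplan` propagates the full distribution of `J` backward through the
levels with two alternating steps:

* **diffusion** — `P(Q_d)` from `P(J_{d-1})`: each mass at `k` moves to
  `k+R+` with probability `q·p`, to `k+R-` with probability `q·(1-p)`,
  and stays (node unsampled) with probability `1-q`; with survival
  probability `γ < 1` the continuation is lost and only the immediate
  reward remains;
* **maximization** — `P(J_d ≤ k) = P(Q_d ≤ k)^b`: the CDF raised to the
  number of available branches (best of `b` i.i.d. action values).

Because the support lives on an integer lattice of size `O(n·d)`, the
cost is `O(n·b·d²)` — a depth-20, branching-5 sub-tree with more than
2·10¹³ nodes evaluates in milliseconds.

Policy families: exhaustive (all `q = 1`), homogeneous (full levels
until the budget runs out, residual spread over the last level),
heterogeneous (free per-level `q`, optimized by projected gradient
ascent under `Σ q_l·b^l = C`), and two-branching-factor policies
(`b1` for the first `d1` levels, `b2` after). Independent verification
comes from exact rational enumeration on small trees and a
Bellman–Monte-Carlo simulator.

## Worked example

Optimal homogeneous allocation in a rich environment (`p = 1/2`) with
capacity `C = 100`:

```sh
$ treeplan optimize --family homogeneous --C 100 --variant rich --n 1
best (2,) -> V = 4.40371763997
```

Sampling two branches per level is optimal: the agent reaches six
levels deep and the best path is worth 4.40 in expectation (each level
contributes at most +1). Neighbouring branching factors lose a lot:

```
 b= 1  V=0.000000  loss=100.0%
 b= 2  V=4.403718  loss=  0.0%
 b= 3  V=3.550494  loss= 19.4%
 b= 5  V=2.918500  loss= 33.7%
 b=10  V=1.998019  loss= 54.6%
```

`b = 1` is worthless — a single path offers no choice, and the
zero-average constraint makes its expected reward exactly zero — while
wide, shallow sampling (`b = 10`) forfeits more than half the
achievable value. Depth dominates breadth.

The probability that the best path is all-high decays with depth when
`p·b ≤ 1`:

```sh
$ treeplan success --p 0.5 --b 2 --d-max 5
fixed point = 0
d,probability
1,0.75
2,0.609375
3,0.516540527344
4,0.449836998247
5,0.399248666999
```

From the library, the same computations:

```python
import treeplan as tp

model = tp.rich(1)                       # p = 1/2, rewards +1 / -1
report = tp.optimize_homogeneous(model, C=100)
print(report.best_params, report.best_value)   # (2,) 4.403717639970775
```

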