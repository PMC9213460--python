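"""Independent verification of the value engine.

Two routes that never touch the diffusion-maximization code path:

* `enumerate_tree_value` computes the exact expectation in rational
  arithmetic by recursively enumerating, for each node, the joint
  weighted outcomes (sampled high / unsampled / sampled low, plus the
  survival coin in discounted runs) of its children sub-trees, taking
  the maximum over explicit outcome tuples rather than CDF powers.
* `mc_tree_value` is a Bellman-Monte-Carlo estimator: instantiate
  random reward realizations on the finite sampled sub-tree, run
  backward induction per realization, and average the root value.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from fractions import Fraction
from math import prod
from typing import List, Optional, Tuple

import numpy as np

from .allocation import capacity_of
from .policies import (
    TWO_B,
    PolicySpec,
    exhaustive_policy,
    heterogeneous_policy,
)
from .rewards import RewardModel, poor, rich

_MAX_TUPLE_COMBOS = 300_000
_MAX_ENUM_NODES = 64
_MAX_MC_NODES = 1_000_000


# ---------------------------------------------------------------------------
# Exact enumeration
# ---------------------------------------------------------------------------

def enumerate_tree_value(model: RewardModel, policy: PolicySpec) -> float:
    """Exact expected optimal-path value of a small sampled sub-tree.

    Works bottom-up over backward levels: the action-value distribution
    of a node is composed exactly (Fraction weights) from its sampled
    reward, the survival coin, and the best of its children's
    distributions, where the maximum is taken by enumerating all
    ``support^branching`` joint child outcomes.  Raises when the
    instance is too large to enumerate.
    """
    model._require_rational()
    if sum(policy.level_sizes()) > _MAX_ENUM_NODES:
        raise ValueError("instance too large for exact enumeration")
    p = Fraction(model.p)
    r_minus = Fraction(model.r_minus)
    gamma = Fraction(policy.gamma)
    q = [Fraction(x) for x in policy.q]

    # Q at the deepest level: reward of a single leaf slot.
    dist = _reward_dist(q[0], p, r_minus)
    dist = _max_of_iid(dist, policy.branching_backward(1))
    for level in range(2, policy.depth + 1):
        dist = _compose_with_reward(dist, q[level - 1], p, r_minus, gamma)
        dist = _max_of_iid(dist, policy.branching_backward(level))
    return float(sum(k * w for k, w in dist.items()))


def _reward_dist(q: Fraction, p: Fraction, r_minus: Fraction):
    dist: dict = {}
    for value, weight in ((Fraction(1), q * p), (Fraction(0), 1 - q),
                          (r_minus, q * (1 - p))):
        if weight:
            dist[value] = dist.get(value, Fraction(0)) + weight
    return dist


def _compose_with_reward(j_dist, q, p, r_minus, gamma):
    """Q = R + (survival ? J : 0), composed exactly."""
    out: dict = {}

    def add(value, weight):
        if weight:
            out[value] = out.get(value, Fraction(0)) + weight

    rewards = ((Fraction(1), q * p), (Fraction(0), 1 - q), (r_minus, q * (1 - p)))
    for jk, jw in j_dist.items():
        for r, rw in rewards:
            add(r + jk, jw * rw * gamma)
    if gamma != 1:
        for r, rw in rewards:
            add(r, rw * (1 - gamma))
    return out


def _max_of_iid(dist, m: int):
    if m == 1:
        return dict(dist)
    if len(dist) ** m > _MAX_TUPLE_COMBOS:
        raise ValueError("instance too large for exact enumeration")
    out: dict = {}
    for combo in itertools.product(dist.items(), repeat=m):
        key = max(k for k, _ in combo)
        weight = prod(w for _, w in combo)
        out[key] = out.get(key, Fraction(0)) + weight
    return out


# ---------------------------------------------------------------------------
# Bellman-Monte-Carlo
# ---------------------------------------------------------------------------

@dataclass
class MCEstimate:
    """Monte-Carlo mean with its standard error."""

    mean: float
    standard_error: float
    runs: int
    seed: int

    def brackets(self, exact: float, n_se: float = 4.0) -> bool:
        """True when ``exact`` lies within ``n_se`` standard errors."""
        return abs(self.mean - exact) <= n_se * max(self.standard_error, 1e-300)


@dataclass
class SampledTree:
    """One realization of sampling a finite sub-tree.

    Per forward level: which node slots received a sample, the revealed
    expected rewards (0 for unsampled slots), and — in discounted runs —
    whether each node's continuation survives.
    """

    level_sizes: Tuple[int, ...]
    sampled: List[np.ndarray]
    rewards: List[np.ndarray]
    survival: Optional[List[np.ndarray]]

    def __post_init__(self) -> None:
        for s, r in zip(self.sampled, self.rewards):
            if np.any((~s) & (r != 0.0)):
                raise ValueError("unsampled node carries a nonzero reward")


def sample_tree(
    model: RewardModel, policy: PolicySpec, rng: np.random.Generator
) -> SampledTree:
    """Draw one joint realization of sampling flags, rewards and coins."""
    sizes = policy.level_sizes()
    p, r_minus = float(model.p), float(model.r_minus)
    gamma = float(policy.gamma)
    q_fwd = [float(x) for x in policy.q_forward]
    sampled, rewards = [], []
    for l, size in enumerate(sizes):
        flags = rng.random(size) < q_fwd[l]
        high = rng.random(size) < p
        rewards.append(flags * np.where(high, 1.0, r_minus))
        sampled.append(flags)
    survival = None
    if gamma < 1.0:
        survival = [rng.random(size) < gamma for size in sizes[:-1]]
    return SampledTree(sizes, sampled, rewards, survival)


def backward_induction(tree: SampledTree, policy: PolicySpec) -> float:
    """Optimal-path value of one realization, leaves to root."""
    d = len(tree.level_sizes)
    v = tree.rewards[d - 1]
    for l in range(d - 1, 0, -1):  # forward level l picks best child at l+1
        j = v.reshape(tree.level_sizes[l - 1], -1).max(axis=1)
        if tree.survival is not None:
            j = j * tree.survival[l - 1]
        v = tree.rewards[l - 1] + j
    return float(v.max())


def mc_tree_value(
    model: RewardModel,
    policy: PolicySpec,
    runs: int,
    seed: int,
    _chunk_cells: int = 5_000_000,
) -> MCEstimate:
    """Bellman-Monte-Carlo estimate of the tree value.

    Vectorizes `sample_tree` + `backward_induction` across batches of
    runs.  Accepts any reward model, including generic real ``p``.
    Identical seeds give identical estimates.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    sizes = policy.level_sizes()
    n_nodes = sum(sizes)
    if n_nodes > _MAX_MC_NODES:
        raise ValueError(f"tree with {n_nodes} nodes is too large to instantiate")
    p, r_minus = float(model.p), float(model.r_minus)
    gamma = float(policy.gamma)
    q_fwd = [float(x) for x in policy.q_forward]
    d = policy.depth
    rng = np.random.default_rng(seed)
    chunk = max(1, min(runs, _chunk_cells // max(sizes)))
    values = np.empty(runs)
    done = 0
    while done < runs:
        n = min(chunk, runs - done)
        rewards = []
        for l, size in enumerate(sizes):
            flags = rng.random((n, size)) < q_fwd[l]
            high = rng.random((n, size)) < p
            rewards.append(flags * np.where(high, 1.0, r_minus))
        v = rewards[d - 1]
        for l in range(d - 1, 0, -1):
            j = v.reshape(n, sizes[l - 1], -1).max(axis=2)
            if gamma < 1.0:
                j = j * (rng.random((n, sizes[l - 1])) < gamma)
            v = rewards[l - 1] + j
        values[done : done + n] = v.max(axis=1)
        done += n
    mean = float(values.mean())
    se = float(values.std(ddof=1) / np.sqrt(runs)) if runs > 1 else float("inf")
    return MCEstimate(mean=mean, standard_error=se, runs=runs, seed=seed)


def mc_random_path_value(
    model: RewardModel,
    policy: PolicySpec,
    runs: int,
    seed: int,
) -> MCEstimate:
    """Cumulative reward of a uniformly random path (no maximization).

    Under the zero-average constraint this averages zero for any model
    and policy; used as a statistical control.
    """
    if runs < 1:
        raise ValueError("runs must be >= 1")
    p, r_minus = float(model.p), float(model.r_minus)
    q_fwd = [float(x) for x in policy.q_forward]
    rng = np.random.default_rng(seed)
    totals = np.zeros(runs)
    for l in range(policy.depth):
        sampled = rng.random(runs) < q_fwd[l]
        high = rng.random(runs) < p
        totals += sampled * np.where(high, 1.0, r_minus)
    mean = float(totals.mean())
    se = float(totals.std(ddof=1) / np.sqrt(runs)) if runs > 1 else float("inf")
    return MCEstimate(mean=mean, standard_error=se, runs=runs, seed=seed)


# ---------------------------------------------------------------------------
# Fixtures
# ---------------------------------------------------------------------------

@dataclass
class Fixture:
    """Reproducible small test instance."""

    kind: str
    seed: int
    model: RewardModel
    policy: PolicySpec
    tree: SampledTree

    def to_config(self) -> dict:
        return {
            "kind": self.kind,
            "seed": self.seed,
            "model": self.model.to_config(),
            "policy": self.policy.to_config(),
        }


def generate_fixture(kind: str, seed: int) -> Fixture:
    """Small reproducible instances within enumeration limits.

    ``tiny_exhaustive``: d <= 3, b <= 3, all q = 1.
    ``tiny_selective``: d <= 3, b <= 2, random dyadic q, optionally
    discounted.
    ``tiny_two_b``: two branching factors <= 2, total depth <= 3,
    dyadic last-level probability.
    ``random_feasible_q``: free random dyadic q whose implied capacity
    is recorded on the policy (so the capacity constraint holds by
    construction).
    """
    rng = np.random.default_rng(seed)
    model = rich(int(rng.integers(1, 3))) if rng.random() < 0.5 else poor(
        int(rng.integers(1, 3))
    )
    if kind == "tiny_exhaustive":
        b = int(rng.integers(1, 4))
        d = int(rng.integers(1, 4))
        policy = exhaustive_policy(b, d)
    elif kind == "tiny_selective":
        b = int(rng.integers(1, 3))
        d = int(rng.integers(1, 4))
        q = tuple(Fraction(int(rng.integers(0, 9)), 8) for _ in range(d))
        gamma = Fraction(int(rng.integers(1, 5)), 4) if rng.random() < 0.5 else 1
        gamma = min(gamma, Fraction(1))
        policy = heterogeneous_policy(b, q, gamma=gamma)
    elif kind == "tiny_two_b":
        b1, b2 = int(rng.integers(1, 3)), int(rng.integers(1, 3))
        d1, d2 = 1, int(rng.integers(1, 3))
        q = (Fraction(int(rng.integers(1, 9)), 8),) + (Fraction(1),) * (d1 + d2 - 1)
        policy = PolicySpec(TWO_B, q=q, b1=b1, b2=b2, d1=d1, d2=d2)
    elif kind == "random_feasible_q":
        b = int(rng.integers(2, 4))
        d = int(rng.integers(2, 4))
        q = tuple(Fraction(int(rng.integers(1, 9)), 8) for _ in range(d))
        policy = heterogeneous_policy(b, q)
        policy = heterogeneous_policy(b, q, C=capacity_of(policy))
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")
    tree = sample_tree(model, policy, rng)
    return Fixture(kind=kind, seed=seed, model=model, policy=policy, tree=tree)
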