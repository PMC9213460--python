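"""Capacity arithmetic: turning (b, C) into concrete sampling policies.

The average capacity constraint states that the expected number of
allocated samples equals the capacity ``C``:

    C = sum_{l=1..d} q_{d-l+1} * b^l                      (single b)
    C = sum_{l=1..d1} q_{..} * b1^l
        + b1^d1 * sum_{l=1..d2} q_{..} * b2^l             (two b)

Homogeneous policies fill levels with probability one until the
residual ``C_r`` no longer covers a full level; the last level is then
sampled with probability ``q1 = C_r / (#nodes in that level)``.  All
arithmetic is exact (`fractions.Fraction`) so that the constraint holds
identically, not merely to tolerance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from numbers import Rational
from typing import Union

from .policies import (
    HOMOGENEOUS,
    RANDOM_BASELINE,
    TWO_B,
    PolicySpec,
    Probability,
)

Capacity = Union[int, float, Fraction]


@dataclass(frozen=True)
class AllocationDerivation:
    """Result of spending capacity level by level.

    ``depth_reached`` is the last (possibly partial) sampled level,
    ``last_level_q`` its sampling probability, ``residual`` the samples
    left when that level is reached (``C_r > 0``), and
    ``expected_cost`` the average number of allocated samples (equals
    ``C`` by construction).
    """

    depth_reached: int
    last_level_q: Fraction
    residual: Fraction
    expected_cost: Fraction

    def __post_init__(self) -> None:
        if not (0 < self.last_level_q <= 1):
            raise ValueError("last-level probability must lie in (0, 1]")
        if self.residual <= 0:
            raise ValueError("residual capacity must be positive")


def capacity_of(policy: PolicySpec) -> Probability:
    """Expected number of allocated samples (the capacity constraint LHS).

    Exact when every ``q`` is rational, floating point otherwise.
    """
    exact = all(isinstance(x, Rational) for x in policy.q)
    total: Probability = Fraction(0) if exact else 0.0
    nodes = 1
    q_fwd = policy.q_forward
    for l in range(1, policy.depth + 1):
        nodes *= policy.branching_forward(l)
        total += q_fwd[l - 1] * nodes
    return total


def derive_homogeneous(b: int, C: Capacity) -> AllocationDerivation:
    """Depth and last-level probability of the homogeneous policy.

    Full levels are stacked while their cumulative cost stays strictly
    below ``C``; the residual ``C_r = C - sum_{l<d'} b^l > 0`` is spread
    over the ``b^d'`` nodes of the last level, ``q1' = C_r / b^d'``.
    When ``C`` exactly fills ``m`` levels the derivation returns
    ``d' = m`` with ``q1' = 1`` rather than a vacuous extra level.
    """
    if b < 1:
        raise ValueError("branching factor must be >= 1")
    C = _as_fraction(C)
    if C < 1:
        raise ValueError(f"capacity must be >= 1, got {C}")
    depth = 1
    spent = Fraction(0)
    level_nodes = b
    while spent + level_nodes < C:
        spent += level_nodes
        level_nodes *= b
        depth += 1
    residual = C - spent
    q1 = residual / level_nodes
    return AllocationDerivation(depth, q1, residual, spent + q1 * level_nodes)


def derive_two_b(b1: int, b2: int, d1: int, C: Capacity) -> AllocationDerivation:
    """Depth ``d2'`` and last-level probability of the two-b policy.

    The first ``d1`` levels branch with ``b1``; the remaining capacity
    is spent on levels of ``b1^d1 * b2^l`` nodes until exhausted.  When
    ``C`` runs out inside the ``b1`` regime the derivation truncates
    there (``d2' = 0``) and reduces to the homogeneous case with
    ``b = b1`` and depth <= ``d1``.
    """
    if b1 < 1 or b2 < 1:
        raise ValueError("branching factors must be >= 1")
    if d1 < 1:
        raise ValueError("d1 must be >= 1")
    C = _as_fraction(C)
    if C <= 0:
        raise ValueError(f"capacity must be positive, got {C}")
    shallow_cost = sum(Fraction(b1) ** l for l in range(1, d1 + 1))
    if shallow_cost >= C:
        return derive_homogeneous(b1, C)
    top_nodes = b1**d1
    spent = shallow_cost
    d2 = 1
    level_nodes = top_nodes * b2
    while spent + level_nodes < C:
        spent += level_nodes
        level_nodes *= b2
        d2 += 1
    residual = C - spent
    q1 = residual / level_nodes
    return AllocationDerivation(d1 + d2, q1, residual, spent + q1 * level_nodes)


def homogeneous_policy(b: int, C: Capacity, gamma: Probability = 1) -> PolicySpec:
    """Homogeneous selective policy for branching ``b`` and capacity ``C``."""
    der = derive_homogeneous(b, C)
    q = (der.last_level_q,) + (Fraction(1),) * (der.depth_reached - 1)
    return PolicySpec(HOMOGENEOUS, q=q, b=b, gamma=gamma, C=_as_fraction(C))


def two_b_policy(b1: int, b2: int, d1: int, C: Capacity) -> PolicySpec:
    """Two-branching-factor homogeneous policy for capacity ``C``."""
    der = derive_two_b(b1, b2, d1, C)
    depth = der.depth_reached
    d1_eff = min(d1, depth)  # capacity may run out inside the b1 regime
    d2_eff = depth - d1_eff
    q = (der.last_level_q,) + (Fraction(1),) * (depth - 1)
    return PolicySpec(TWO_B, q=q, b1=b1, b2=b2, d1=d1_eff, d2=d2_eff,
                      C=_as_fraction(C))


def random_allocation(b: int, C: Capacity) -> PolicySpec:
    """Uniform-probability baseline on a depth-capped tree.

    Every node of the tree of depth ``d = 2*floor(ln C / ln b) + 3``
    receives a sample with the same probability, chosen so that the
    capacity constraint holds.
    """
    if b < 2:
        raise ValueError("random baseline requires b >= 2")
    C = _as_fraction(C)
    if C < 1:
        raise ValueError(f"capacity must be >= 1, got {C}")
    d = default_depth_cap(b, C)
    nodes = sum(Fraction(b) ** l for l in range(1, d + 1))
    q_uniform = C / nodes
    if q_uniform > 1:
        raise ValueError(
            f"capacity {C} exceeds the {nodes} nodes of the depth-{d} tree"
        )
    return PolicySpec(RANDOM_BASELINE, q=(q_uniform,) * d, b=b,
                      C=_as_fraction(C))


def default_depth_cap(b: int, C: Capacity) -> int:
    """Depth cap ``2*floor(ln C / ln b) + 3`` for free-q and random policies."""
    if b < 2:
        raise ValueError("depth cap requires b >= 2")
    return 2 * math.floor(math.log(float(C)) / math.log(b)) + 3


def _as_fraction(C: Capacity) -> Fraction:
    return C if isinstance(C, Fraction) else Fraction(C)
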