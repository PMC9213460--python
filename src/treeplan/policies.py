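"""Sample-allocation policy specifications.

A policy fixes which nodes of the infinite decision tree receive a
sample: a branching factor per level (how many children of every
reached node are considered) and a per-level Bernoulli sampling
probability.  Probabilities are stored in *backward* order, matching
the backward value recursion: ``q[0]`` (written ``q1``) is the deepest
sampled level, ``q[-1]`` is the first level below the root.

Families
--------
``exhaustive``
    All ``q = 1`` on a depth-``d``, branching-``b`` sub-tree.
``homogeneous``
    Single ``b``; all levels fully sampled except the last, whose
    probability absorbs the capacity residual.
``heterogeneous``
    Single ``b``; free per-level probabilities under the average
    capacity constraint.
``two_b``
    Branching ``b1`` for the first ``d1`` levels, ``b2`` for the
    following ``d2``; only the last level may be partially sampled.
``random_baseline``
    Single ``b``; one uniform sampling probability on a depth-capped
    tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Optional, Tuple, Union

Probability = Union[Fraction, float]

EXHAUSTIVE = "exhaustive"
HOMOGENEOUS = "homogeneous"
HETEROGENEOUS = "heterogeneous"
TWO_B = "two_b"
RANDOM_BASELINE = "random_baseline"

_FAMILIES = (EXHAUSTIVE, HOMOGENEOUS, HETEROGENEOUS, TWO_B, RANDOM_BASELINE)

_Q_TOL = 1e-12


@dataclass(frozen=True)
class PolicySpec:
    """Fully resolved allocation policy.

    ``q`` is the per-level sampling probability vector in backward
    order (``q[0]`` = deepest level).  Single-``b`` families set ``b``;
    the two-``b`` family sets ``b1, b2, d1, d2`` with total depth
    ``d1 + d2``.  ``gamma`` is the per-level survival probability
    (``1`` = undiscounted).  ``C`` records the capacity the policy was
    derived from, when applicable.
    """

    family: str
    q: Tuple[Probability, ...]
    b: Optional[int] = None
    b1: Optional[int] = None
    b2: Optional[int] = None
    d1: Optional[int] = None
    d2: Optional[int] = None
    gamma: Probability = 1
    C: Optional[Probability] = None

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise ValueError(f"unknown policy family {self.family!r}")
        if len(self.q) == 0:
            raise ValueError("policy must sample at least one level")
        for qi in self.q:
            if not (-_Q_TOL <= qi <= 1 + _Q_TOL):
                raise ValueError(f"sampling probability {qi} outside [0, 1]")
        if not (0 <= self.gamma <= 1):
            raise ValueError(f"gamma {self.gamma} outside [0, 1]")
        if self.family == TWO_B:
            if None in (self.b1, self.b2, self.d1, self.d2):
                raise ValueError("two_b policy requires b1, b2, d1, d2")
            if self.d1 < 1 or self.d2 < 0:  # type: ignore[operator]
                raise ValueError("two_b policy requires d1 >= 1, d2 >= 0")
            if self.d1 + self.d2 != len(self.q):  # type: ignore[operator]
                raise ValueError("two_b policy depth d1 + d2 must match len(q)")
            if self.gamma != 1:
                raise ValueError("discounting is only supported for single-b policies")
            if self.b1 < 1 or self.b2 < 1:  # type: ignore[operator]
                raise ValueError("branching factors must be >= 1")
        else:
            if self.b is None or self.b < 1:
                raise ValueError("single-b policy requires integer b >= 1")
        if self.family == EXHAUSTIVE and any(qi != 1 for qi in self.q):
            raise ValueError("exhaustive policy requires all q = 1")

    @property
    def depth(self) -> int:
        """Number of sampled levels."""
        return len(self.q)

    @property
    def q_forward(self) -> Tuple[Probability, ...]:
        """Sampling probabilities in natural level order (root first)."""
        return tuple(reversed(self.q))

    def branching_backward(self, level: int) -> int:
        """Branching factor applied at backward level ``level`` (1-based).

        Backward level 1 is the deepest sampled level; for two-``b``
        policies the last ``d2`` backward levels use ``b2`` and the
        remaining ``d1`` use ``b1``.
        """
        if not 1 <= level <= self.depth:
            raise ValueError(f"backward level {level} outside 1..{self.depth}")
        if self.family == TWO_B:
            return int(self.b2 if level <= self.d2 else self.b1)  # type: ignore[arg-type]
        return int(self.b)  # type: ignore[arg-type]

    def branching_forward(self, level: int) -> int:
        """Branching factor of forward level ``level`` (1-based, root first)."""
        return self.branching_backward(self.depth - level + 1)

    def level_sizes(self) -> Tuple[int, ...]:
        """Number of considered nodes at each forward level."""
        sizes = []
        size = 1
        for l in range(1, self.depth + 1):
            size *= self.branching_forward(l)
            sizes.append(size)
        return tuple(sizes)

    def is_rational(self) -> bool:
        """True when every probability is exactly representable."""
        return all(isinstance(x, Rational) for x in (*self.q, self.gamma))

    def to_config(self) -> dict:
        cfg: dict = {"family": self.family, "q_backward": [float(x) for x in self.q]}
        for key in ("b", "b1", "b2", "d1", "d2"):
            val = getattr(self, key)
            if val is not None:
                cfg[key] = int(val)
        if self.gamma != 1:
            cfg["gamma"] = float(self.gamma)
        if self.C is not None:
            cfg["C"] = float(self.C)
        return cfg


def exhaustive_policy(b: int, d: int) -> PolicySpec:
    """Fully sample a depth-``d``, branching-``b`` sub-tree."""
    if d < 1:
        raise ValueError("depth must be >= 1")
    return PolicySpec(EXHAUSTIVE, q=(Fraction(1),) * d, b=b)


def heterogeneous_policy(
    b: int,
    q: "tuple[Probability, ...] | list[Probability]",
    *,
    order: str = "backward",
    gamma: Probability = 1,
    C: Optional[Probability] = None,
    family: str = HETEROGENEOUS,
) -> PolicySpec:
    """Free per-level sampling probabilities with a single ``b``.

    ``order="forward"`` accepts the vector in natural root-first order.
    """
    if order == "forward":
        q = tuple(reversed(tuple(q)))
    elif order == "backward":
        q = tuple(q)
    else:
        raise ValueError("order must be 'backward' or 'forward'")
    return PolicySpec(family, q=q, b=b, gamma=gamma, C=C)
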