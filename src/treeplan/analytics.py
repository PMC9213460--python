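"""Closed-form results around the value recursion.

Covers the success-probability recursion (probability that the best
path carries the maximal cumulative reward ``d``), its large-depth
fixed point with the ``p*b > 1`` threshold, the count of distinct
lattice states per level that fixes the algorithm's complexity, and the
relative-loss metric used to compare policies against the optimum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List

from scipy.optimize import brentq


@dataclass(frozen=True)
class SuccessCurve:
    """``P(J_d = d)`` for ``d = 1..d_max`` and its large-depth limit."""

    p: float
    b: int
    values: List[float]
    limit: float


def success_probability(p: float, b: int, d_max: int) -> SuccessCurve:
    """Iterate the success-probability recursion.

    ``P(J_1 = 1) = 1 - (1-p)^b`` and, for deeper trees,
    ``P(J_d = d) = 1 - (1 - p * P(J_{d-1} = d-1))^b``: the best path has
    all-high rewards iff at least one branch carries a high reward
    followed by an all-high path.
    """
    _check(p, b)
    if d_max < 1:
        raise ValueError("d_max must be >= 1")
    values = [1.0 - (1.0 - p) ** b]
    for _ in range(1, d_max):
        values.append(1.0 - (1.0 - p * values[-1]) ** b)
    return SuccessCurve(p=p, b=b, values=values, limit=success_fixed_point(p, b))


def success_fixed_point(p: float, b: int, tol: float = 1e-12) -> float:
    """Large-depth limit of ``P(J_d = d)``.

    Solves ``1 - P = (1 - p*P)^b`` on [0, 1].  ``P = 0`` is always a
    root; a second, attracting root in (0, 1] exists exactly when the
    slope condition ``p*b > 1`` holds, in which case an all-high path
    survives with positive probability no matter how deep the tree.
    """
    _check(p, b)
    if p * b <= 1.0:
        return 0.0

    def f(P: float) -> float:
        return 1.0 - P - (1.0 - p * P) ** b

    # f has positive slope at 0 when p*b > 1 and f(1) = -(1-p)^b < 0,
    # so the nontrivial root is bracketed away from the trivial P = 0.
    return float(brentq(f, 1e-15, 1.0, xtol=tol))


def distinct_state_count(n: int, s: int) -> int:
    """Number of distinct cumulative-reward values at level ``s``.

    The lattice values are ``k = i - n*j`` with ``i, j >= 0`` and
    ``i + j <= s``; collisions between (i, j) pairs reduce the count to
    ``(s+1)(s+2)/2`` below the diagonal (``s < n``) and to
    ``(n+1)s - n(n-1)/2 + 1`` from ``s >= n`` onward, i.e. linear in
    ``s``.
    """
    if n < 1 or s < 1:
        raise ValueError("n and s must be >= 1")
    if s < n:
        return (s + 1) * (s + 2) // 2
    return (n + 1) * s - n * (n - 1) // 2 + 1


def subtree_node_count(b: int, d: int) -> int:
    """Nodes below the root of a depth-``d``, branching-``b`` sub-tree."""
    if b < 1 or d < 1:
        raise ValueError("b and d must be >= 1")
    if b == 1:
        return d
    return (b ** (d + 1) - b) // (b - 1)


def relative_loss(v_opt: float, v: float) -> float:
    """Percentage loss ``100 * (v_opt - v) / v_opt`` of a policy vs the optimum."""
    if v_opt <= 0:
        raise ValueError("relative loss requires a positive optimal value")
    return 100.0 * (v_opt - v) / v_opt


def _check(p: float, b: int) -> None:
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    if b < 1:
        raise ValueError("b must be >= 1")
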