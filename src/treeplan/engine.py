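"""Exact value computation by the diffusion-maximization recursion.

The value of playing a sampled sub-tree is the expectation of the
cumulative reward ``J_d`` of the best path.  Instead of enumerating the
exponentially many reward realizations, the engine propagates the full
probability distribution of ``J`` backward through the levels:

* a *diffusion* step turns ``P(J_{d-1})`` into the action-value
  distribution ``P(Q_d)`` by convolving with the immediate-reward
  distribution of one node (sampled with probability ``q``, surviving
  with probability ``gamma``);
* a *maximization* step turns ``P(Q_d)`` into ``P(J_d)`` by raising the
  CDF to the power of the number of available branches (distribution of
  the maximum of i.i.d. draws).

For the rational reward families the support lives on an integer
lattice (``k = i - n*j`` for rich models, ``n*k = n*i - j`` for poor
ones), so distributions are stored as dense arrays over consecutive
integer keys.  Total cost is O(n * b * d^2) instead of the O(b^d) of
naive backward induction on the tree.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .policies import PolicySpec
from .rewards import RewardModel

logger = logging.getLogger(__name__)

ROLE_STATE = "J"
ROLE_ACTION = "Q"

_NORM_TOL = 1e-12


@dataclass
class ValueDistribution:
    """Probability table of ``J`` (or ``Q``) on the integer lattice.

    ``probs[i]`` is the probability of the lattice key ``lo + i``; the
    true cumulative reward of key ``k`` is ``k / scale``.
    """

    probs: np.ndarray
    lo: int
    scale: int
    depth: int
    role: str

    @property
    def hi(self) -> int:
        return self.lo + len(self.probs) - 1

    def keys(self) -> np.ndarray:
        return np.arange(self.lo, self.hi + 1)

    def mean(self) -> float:
        """Expectation of the true (unscaled) value.

        Uses exactly-rounded summation so that symmetric distributions
        (e.g. any b = 1 policy in a rich n = 1 environment) average to
        zero exactly.
        """
        terms = self.keys() * self.probs
        return math.fsum(terms) / self.scale

    def probability_of(self, value: "float | int") -> float:
        """Probability mass at a true (unscaled) value, 0 off-lattice."""
        scaled = value * self.scale
        k = int(round(scaled))
        if abs(scaled - k) > 1e-9 or not self.lo <= k <= self.hi:
            return 0.0
        return float(self.probs[k - self.lo])

    def support_size(self) -> int:
        """Number of lattice keys carrying nonzero mass."""
        return int(np.count_nonzero(self.probs))

    def as_dict(self) -> "dict[int, float]":
        """Sparse ``{integer key: probability}`` view (nonzero mass only)."""
        return {
            int(k): float(p)
            for k, p in zip(self.keys(), self.probs)
            if p != 0.0
        }

    def to_rows(self) -> "list[tuple[float, float]]":
        """(value, probability) pairs for CSV export, nonzero mass only."""
        return [
            (k / self.scale, float(p))
            for k, p in zip(self.keys(), self.probs)
            if p != 0.0
        ]


@dataclass
class ValueResult:
    """Tree value ``V = E(J_d)`` with its terminal distribution."""

    value: float
    terminal: ValueDistribution
    policy: PolicySpec
    model: RewardModel


def initial_level_distribution(
    model: RewardModel, q1: float, b_eff: int
) -> ValueDistribution:
    """Distribution of ``J_1``, the value of the deepest sampled level.

    Each of the ``b_eff`` leaf branches carries the action-value ``Q_1``
    with ``P(Q_1=R+) = q1*p``, ``P(Q_1=0) = 1-q1``,
    ``P(Q_1=R-) = q1*(1-p)``; the best of the ``b_eff`` i.i.d. draws
    gives ``J_1``.  ``b_eff`` is ``b2`` for two-b policies (the deepest
    levels branch with ``b2``).
    """
    q1 = _check_probability(q1, "q1")
    if b_eff < 1:
        raise ValueError("branching factor must be >= 1")
    scale = model.lattice_scale
    up, down = model.lattice_up, model.lattice_down
    p = float(model.p)
    probs = np.zeros(up - down + 1)
    probs[0] = q1 * (1.0 - p)       # key `down`  (low reward)
    probs[-down] = 1.0 - q1         # key 0      (unsampled)
    probs[-1] = q1 * p              # key `up`   (high reward)
    qdist = ValueDistribution(probs, lo=down, scale=scale, depth=1, role=ROLE_ACTION)
    return maximization_step(qdist, b_eff)


def diffusion_step(
    model: RewardModel,
    prior: ValueDistribution,
    q: float,
    gamma: float = 1.0,
) -> ValueDistribution:
    """Map ``P(J_{d-1})`` to the action-value distribution ``P(Q_d)``.

    Conditional on surviving (probability ``gamma``), the continuation
    value ``J_{d-1} = k`` moves to ``k + R+`` with probability ``q*p``,
    to ``k + R-`` with probability ``q*(1-p)``, and stays at ``k`` with
    probability ``1-q`` (node not sampled).  On death (probability
    ``1-gamma``) only the immediate reward remains, adding mass at
    ``R+``, ``0`` and ``R-``.
    """
    if prior.role != ROLE_STATE:
        raise ValueError("diffusion expects a state-value (J) distribution")
    if prior.scale != model.lattice_scale:
        raise ValueError("lattice scale mismatch between prior and model")
    q = _check_probability(q, "q")
    gamma = _check_probability(gamma, "gamma")
    up, down = model.lattice_up, model.lattice_down
    p = float(model.p)
    lo = prior.lo + down
    hi = prior.hi + up
    if gamma < 1.0:  # death mass lands on {down, 0, up} regardless of prior
        lo, hi = min(lo, down), max(hi, up)
    out = np.zeros(hi - lo + 1)
    m = prior.probs
    i0 = prior.lo - lo  # offset of an unshifted copy
    out[i0 : i0 + len(m)] += (1.0 - q) * gamma * m
    out[i0 + up : i0 + up + len(m)] += q * p * gamma * m
    out[i0 + down : i0 + down + len(m)] += q * (1.0 - p) * gamma * m
    if gamma < 1.0:
        out[up - lo] += q * p * (1.0 - gamma)
        out[-lo] += (1.0 - q) * (1.0 - gamma)
        out[down - lo] += q * (1.0 - p) * (1.0 - gamma)
    return ValueDistribution(out, lo=lo, scale=prior.scale,
                             depth=prior.depth + 1, role=ROLE_ACTION)


def maximization_step(qdist: ValueDistribution, b_level: int) -> ValueDistribution:
    """Map ``P(Q_d)`` to ``P(J_d)``: best of ``b_level`` i.i.d. draws.

    ``P(J_d <= k) = P(Q_d <= k)^b`` at every lattice key, so the output
    mass is the difference of consecutive CDF powers.
    """
    if qdist.role != ROLE_ACTION:
        raise ValueError("maximization expects an action-value (Q) distribution")
    if b_level < 1:
        raise ValueError("branching factor must be >= 1")
    if b_level == 1:  # max over one option: exact identity, no CDF round-trip
        return ValueDistribution(qdist.probs.copy(), lo=qdist.lo,
                                 scale=qdist.scale, depth=qdist.depth,
                                 role=ROLE_STATE)
    cdf = np.cumsum(qdist.probs)
    cb = cdf ** b_level
    probs = np.diff(cb, prepend=0.0)
    np.clip(probs, 0.0, None, out=probs)
    total = probs.sum()
    if not np.isfinite(total) or abs(total - 1.0) > 1e-6:
        raise ArithmeticError(f"distribution mass drifted to {total}")
    if abs(total - 1.0) > _NORM_TOL:
        logger.debug("renormalizing P(J_%d): mass %.17g", qdist.depth, total)
    probs /= total  # renormalized at every level to curb drift in deep trees
    return ValueDistribution(probs, lo=qdist.lo, scale=qdist.scale,
                             depth=qdist.depth, role=ROLE_STATE)


def tree_value(model: RewardModel, policy: PolicySpec) -> ValueResult:
    """Value of playing a sampled sub-tree: ``V = E(J_d)``.

    Runs the backward recursion: the deepest level's ``J_1`` first
    (using ``q[0]`` and the deepest branching factor), then alternating
    diffusion and maximization up to the root.
    """
    model._require_rational()
    gamma = float(policy.gamma)
    q = [float(x) for x in policy.q]
    dist = initial_level_distribution(model, q[0], policy.branching_backward(1))
    for level in range(2, policy.depth + 1):
        dist = diffusion_step(model, dist, q[level - 1], gamma)
        dist = maximization_step(dist, policy.branching_backward(level))
    return ValueResult(value=dist.mean(), terminal=dist, policy=policy, model=model)


def heterogeneous_values(
    model: RewardModel,
    b: int,
    q_batch: np.ndarray,
    gamma: float = 1.0,
) -> np.ndarray:
    """Values of a batch of heterogeneous policies sharing ``b`` and depth.

    ``q_batch`` has shape ``(m, d)`` with backward-order rows; the
    recursion is run once on an ``(m, keys)`` probability matrix, which
    is what makes finite-difference gradients over ``q`` affordable.
    Row ``i`` equals ``tree_value`` of the policy with ``q_batch[i]``.
    """
    model._require_rational()
    q_batch = np.asarray(q_batch, dtype=float)
    if q_batch.ndim != 2:
        raise ValueError("q_batch must be a 2-D (policies x levels) array")
    if b < 1:
        raise ValueError("branching factor must be >= 1")
    if np.any(q_batch < -1e-9) or np.any(q_batch > 1 + 1e-9):
        raise ValueError("sampling probabilities outside [0, 1]")
    q_batch = np.clip(q_batch, 0.0, 1.0)
    m, d = q_batch.shape
    up, down = model.lattice_up, model.lattice_down
    p = float(model.p)
    gamma = _check_probability(gamma, "gamma")

    # J_1 for every row.
    q1 = q_batch[:, 0]
    width = up - down + 1
    probs = np.zeros((m, width))
    probs[:, 0] = q1 * (1.0 - p)
    probs[:, -down] = 1.0 - q1
    probs[:, -1] = q1 * p
    lo = down
    probs = _batched_maximization(probs, b)
    for level in range(2, d + 1):
        q = q_batch[:, level - 1][:, None]
        n = probs.shape[1]
        out = np.zeros((m, n + width - 1))
        i0 = -down
        out[:, i0 : i0 + n] += (1.0 - q) * gamma * probs
        out[:, i0 + up : i0 + up + n] += q * p * gamma * probs
        out[:, 0:n] += q * (1.0 - p) * gamma * probs
        lo += down
        if gamma < 1.0:
            out[:, up - lo] += q[:, 0] * p * (1.0 - gamma)
            out[:, -lo] += (1.0 - q[:, 0]) * (1.0 - gamma)
            out[:, down - lo] += q[:, 0] * (1.0 - p) * (1.0 - gamma)
        probs = _batched_maximization(out, b)
    keys = np.arange(lo, lo + probs.shape[1])
    return (probs @ keys) / model.lattice_scale


def _batched_maximization(probs: np.ndarray, b: int) -> np.ndarray:
    cdf = np.cumsum(probs, axis=1)
    cb = cdf ** b
    out = np.diff(cb, prepend=0.0, axis=1)
    np.clip(out, 0.0, None, out=out)
    out /= out.sum(axis=1, keepdims=True)
    return out


def _check_probability(x: float, name: str) -> float:
    x = float(x)
    if not -1e-9 <= x <= 1.0 + 1e-9:
        raise ValueError(f"{name} = {x} outside [0, 1]")
    return min(max(x, 0.0), 1.0)
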