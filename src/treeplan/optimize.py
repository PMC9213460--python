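"""Policy optimization within each allocation family.

* Homogeneous: scan the branching factor ``b`` over a grid, deriving
  depth and last-level probability from the capacity each time.
* Two-b: exhaustive grid over ``(b1, b2, d1)``.
* Heterogeneous: projected gradient ascent on the per-level sampling
  probabilities ``q`` under the linear capacity constraint
  ``sum_l q_l b^l = C`` and the box ``0 <= q_l <= 1``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .allocation import (
    Capacity,
    default_depth_cap,
    homogeneous_policy,
    two_b_policy,
)
from .engine import heterogeneous_values, tree_value
from .policies import HETEROGENEOUS, PolicySpec, heterogeneous_policy
from .rewards import RewardModel


class ProjectionError(RuntimeError):
    """Raised when the clip/re-project loop fails to reach feasibility."""


@dataclass(frozen=True)
class AscentSettings:
    """Hyperparameters of the projected gradient ascent.

    ``step_size`` is the finite-difference discretization of the
    gradient, ``learning_rate`` the ascent step, ``tolerance`` the
    minimum per-iteration value improvement before stopping.
    """

    step_size: float = 1e-7
    learning_rate: float = 1e-3
    max_iterations: int = 1_000_000
    tolerance: float = 1e-9
    central_differences: bool = False
    init: str = "uniform"  # uniform | homogeneous | random
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.step_size, self.learning_rate, self.tolerance) <= 0:
            raise ValueError("step size, learning rate and tolerance must be > 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")


@dataclass
class OptimizerReport:
    """Outcome of a family-level optimization."""

    family: str
    best_params: tuple
    best_value: float
    candidates: List[Tuple[tuple, float]] = field(default_factory=list)
    trajectory: List[float] = field(default_factory=list)
    settings: dict = field(default_factory=dict)
    best_policy: Optional[PolicySpec] = None

    def to_config(self) -> dict:
        cfg = {
            "family": self.family,
            "best_params": list(self.best_params),
            "best_value": self.best_value,
            "settings": self.settings,
        }
        if self.best_policy is not None:
            cfg["best_policy"] = self.best_policy.to_config()
        return cfg


def optimize_homogeneous(
    model: RewardModel,
    C: Capacity,
    b_range: Iterable[int] = range(1, 21),
    gamma: float = 1.0,
) -> OptimizerReport:
    """Best branching factor for homogeneous selective allocation.

    Evaluates the capacity-derived homogeneous policy for every ``b``
    in the grid; ties break toward the smallest ``b`` (the deeper
    policy).
    """
    b_values = sorted(set(int(b) for b in b_range))
    if not b_values:
        raise ValueError("empty branching-factor range")
    candidates: List[Tuple[tuple, float]] = []
    best_b, best_v, best_policy = None, -math.inf, None
    for b in b_values:
        policy = homogeneous_policy(b, C, gamma=gamma)
        v = tree_value(model, policy).value
        candidates.append(((b,), v))
        if v > best_v:
            best_b, best_v, best_policy = b, v, policy
    return OptimizerReport(
        family="homogeneous",
        best_params=(best_b,),
        best_value=best_v,
        candidates=candidates,
        settings={"C": float(C), "gamma": gamma, "b_range": b_values},
        best_policy=best_policy,
    )


def default_two_b_grid(C: Capacity, b_max: int = 10) -> dict:
    """Grid spec covering the capacity-reachable switching depths."""
    d1_max = max(1, math.ceil(math.log(float(C), 2)) + 1)
    return {
        "b1": range(1, b_max + 1),
        "b2": range(1, b_max + 1),
        "d1": range(1, d1_max + 1),
    }


def optimize_two_b(
    model: RewardModel,
    C: Capacity,
    b1_range: Iterable[int] = range(1, 11),
    b2_range: Iterable[int] = range(1, 11),
    d1_range: Iterable[int] = range(1, 11),
) -> OptimizerReport:
    """Exhaustive grid search over the two-branching-factor family.

    Ties break lexicographically (smallest ``b1``, then ``b2``, then
    ``d1``); the grid is scanned in that order, so a later candidate
    replaces the incumbent only on strict improvement.
    """
    b1s, b2s, d1s = (sorted(set(map(int, r))) for r in (b1_range, b2_range, d1_range))
    if not (b1s and b2s and d1s):
        raise ValueError("empty two-b grid")
    candidates: List[Tuple[tuple, float]] = []
    best_params, best_v, best_policy = None, -math.inf, None
    for b1 in b1s:
        for b2 in b2s:
            for d1 in d1s:
                policy = two_b_policy(b1, b2, d1, C)
                v = tree_value(model, policy).value
                candidates.append(((b1, b2, d1), v))
                if v > best_v:
                    best_params, best_v, best_policy = (b1, b2, d1), v, policy
    return OptimizerReport(
        family="two_b",
        best_params=best_params,
        best_value=best_v,
        candidates=candidates,
        settings={"C": float(C), "b1": b1s, "b2": b2s, "d1": d1s},
        best_policy=best_policy,
    )


def project_to_constraint(
    q: Sequence[float],
    b: int,
    C: float,
    max_rounds: Optional[int] = None,
    tol: float = 1e-9,
) -> np.ndarray:
    """Project ``q`` (forward level order) onto the capacity hyperplane.

    The orthogonal projection onto ``sum_l q_l b^l = C`` moves ``q``
    parallel to the weight vector ``w_l = b^l``.  Components pushed
    outside [0, 1] are clipped to the nearer bound and the projection
    repeated; when this loop has not settled after ``10 * d`` rounds
    (it can stall far from the feasible set) the exact KKT form of the
    projection onto the box-hyperplane intersection,
    ``q = clip(q0 + theta * w, 0, 1)`` with ``theta`` solved by
    bisection, is used instead.  Raises `ProjectionError` when the
    intersection is empty (``C`` outside ``[0, sum_l b^l]``).
    """
    q0 = np.asarray(q, dtype=float)
    d = len(q0)
    if max_rounds is None:
        max_rounds = 10 * d
    C = float(C)
    w = np.array([float(b) ** l for l in range(1, d + 1)])
    if not -tol <= C <= w.sum() + tol:
        raise ProjectionError(
            f"capacity {C} outside the reachable range [0, {w.sum():.0f}] "
            f"of the depth-{d} box"
        )
    wsq = w @ w
    atol = tol * max(1.0, abs(C))
    q = q0
    for _ in range(max_rounds):
        q = q + w * (C - w @ q) / wsq
        clipped = np.clip(q, 0.0, 1.0)
        feasible_box = np.array_equal(clipped, q)
        q = clipped
        if feasible_box and abs(w @ q - C) <= atol:
            return q
    return _kkt_projection(q0, w, C)


def _kkt_projection(q0: np.ndarray, w: np.ndarray, C: float) -> np.ndarray:
    """Exact projection onto {0 <= q <= 1, w.q = C} via theta-bisection."""

    def spent(theta: float) -> float:
        return w @ np.clip(q0 + theta * w, 0.0, 1.0)

    lo = float(np.min((0.0 - q0) / w)) - 1.0   # everything at the lower bound
    hi = float(np.max((1.0 - q0) / w)) + 1.0   # everything at the upper bound
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if spent(mid) < C:
            lo = mid
        else:
            hi = mid
    theta = 0.5 * (lo + hi)
    q = np.clip(q0 + theta * w, 0.0, 1.0)
    free = (q > 0.0) & (q < 1.0)
    if free.any():  # polish theta on the settled active set
        wf = w[free]
        theta = (C - w[~free] @ q[~free] - wf @ q0[free]) / (wf @ wf)
        q[free] = np.clip(q0[free] + theta * wf, 0.0, 1.0)
    return q


def optimize_heterogeneous(
    model: RewardModel,
    C: Capacity,
    b: int,
    d: Optional[int] = None,
    settings: Optional[AscentSettings] = None,
) -> OptimizerReport:
    """Projected gradient ascent on the per-level probabilities ``q``.

    The depth defaults to ``2*floor(ln C / ln b) + 3`` so that samples
    can spread well beyond the levels a homogeneous policy reaches.
    Each iteration estimates the gradient of the tree value by finite
    differences, projects it onto the capacity hyperplane, steps, and
    restores feasibility by the clip/re-project loop; it stops when the
    value improves by less than the tolerance or the iteration budget is
    spent.
    """
    settings = settings or AscentSettings()
    C_f = float(C)
    if d is None:
        d = default_depth_cap(b, C_f)
    w = np.array([float(b) ** l for l in range(1, d + 1)])
    if C_f > w.sum() + 1e-9:
        raise ValueError(
            f"no feasible q: capacity {C_f} exceeds the {w.sum():.0f} nodes "
            f"of the depth-{d} tree"
        )
    q = _initial_q(settings, d, b, C_f)
    gamma = 1.0

    def value_of(q_fwd: np.ndarray) -> float:
        batch = np.clip(q_fwd, 0.0, 1.0)[::-1][None, :]
        return float(heterogeneous_values(model, b, batch, gamma)[0])

    v = value_of(q)
    trajectory = [v]
    dq, eta = settings.step_size, settings.learning_rate
    for _ in range(settings.max_iterations):
        g = _finite_difference_gradient(model, b, gamma, q, v, dq,
                                        settings.central_differences)
        g_proj = g - w * (w @ g) / (w @ w)
        q_new = project_to_constraint(q + eta * g_proj, b, C_f)
        v_new = value_of(q_new)
        if v_new <= v + settings.tolerance:
            if v_new > v:
                q, v = q_new, v_new
                trajectory.append(v)
            break
        q, v = q_new, v_new
        trajectory.append(v)

    best_policy = heterogeneous_policy(b, np.clip(q, 0.0, 1.0),
                                       order="forward", C=C_f)
    return OptimizerReport(
        family=HETEROGENEOUS,
        best_params=tuple(float(x) for x in q),
        best_value=v,
        trajectory=trajectory,
        settings={"C": C_f, "b": b, "d": d, "step_size": dq,
                  "learning_rate": eta, "tolerance": settings.tolerance,
                  "max_iterations": settings.max_iterations,
                  "init": settings.init, "seed": settings.seed},
        best_policy=best_policy,
    )


def _finite_difference_gradient(model, b, gamma, q, v0, dq, central):
    """Finite-difference gradient of the value w.r.t. forward-order q.

    All perturbed policies are evaluated in a single batched recursion.
    Components within ``dq`` of the upper box bound use a backward
    difference so the evaluated vectors stay inside [0, 1].
    """
    d = len(q)
    if central:
        upper = np.minimum(q[None, :] + dq * np.eye(d), 1.0)
        lower = np.maximum(q[None, :] - dq * np.eye(d), 0.0)
        batch = np.vstack([upper, lower])[:, ::-1]
        vals = heterogeneous_values(model, b, batch, gamma)
        denom = np.diag(upper) - np.diag(lower)
        with np.errstate(invalid="ignore"):
            g = np.where(denom > 0, (vals[:d] - vals[d:]) / denom, 0.0)
        return g
    forward = q + dq <= 1.0
    sign = np.where(forward, 1.0, -1.0)
    batch = (q[None, :] + dq * np.diag(sign))[:, ::-1]
    vals = heterogeneous_values(model, b, batch, gamma)
    return sign * (vals - v0) / dq


def _initial_q(settings: AscentSettings, d: int, b: int, C: float) -> np.ndarray:
    if settings.init == "uniform":
        q0 = np.full(d, 0.5)
    elif settings.init == "homogeneous":
        der_q = np.zeros(d)
        spent, nodes = 0.0, 1.0
        for l in range(d):
            nodes *= b
            der_q[l] = min(1.0, max(0.0, (C - spent) / nodes))
            spent += der_q[l] * nodes
        q0 = der_q
    elif settings.init == "random":
        rng = np.random.default_rng(settings.seed)
        q0 = rng.uniform(0.0, 1.0, size=d)
    else:
        raise ValueError(f"unknown init policy {settings.init!r}")
    return project_to_constraint(q0, b, C)
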