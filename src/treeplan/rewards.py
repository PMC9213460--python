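"""Binary reward statistics of sampled tree nodes.

Sampling a node reveals whether visiting it would yield a high expected
reward ``R+ = +1`` (with probability ``p``) or a low expected reward
``R- = -p/(1-p)`` (with probability ``1-p``).  The magnitudes are tied by
the *zero-average constraint* ``p*R+ + (1-p)*R- = 0``, so an unsampled
node (expected reward 0) is statistically indistinguishable, in
expectation, from a sampled one before its outcome is seen.

The exact value engine only handles the rational families

* *rich*: ``p = n/(n+1)`` with ``R- = -n``,
* *poor*: ``p = 1/(n+1)`` with ``R- = -1/n``,

for a positive integer ``n``, because these keep the cumulative-reward
support on an integer lattice.  A *generic* real ``p`` is accepted only
by the Monte-Carlo oracle.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Union

RICH = "rich"
POOR = "poor"
GENERIC = "generic"

_VARIANTS = (RICH, POOR, GENERIC)


@dataclass(frozen=True)
class RewardModel:
    """Reward statistics of a sampled node.

    Attributes
    ----------
    variant:
        ``"rich"``, ``"poor"`` or ``"generic"``.
    p:
        Probability that a sample reveals the high reward.  An exact
        `~fractions.Fraction` for the rational variants, a float for
        ``"generic"``.
    r_minus:
        Magnitude of the low reward (negative).  Exact for rational
        variants.
    n:
        Rational index (``p = n/(n+1)`` rich, ``p = 1/(n+1)`` poor);
        ``None`` for generic models.
    r_plus:
        High reward, fixed to ``+1``.
    """

    variant: str
    p: Union[Fraction, float]
    r_minus: Union[Fraction, float]
    n: Optional[int] = None
    r_plus: int = 1

    def __post_init__(self) -> None:
        if self.variant not in _VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if not (0 < self.p < 1):
            raise ValueError(f"p must lie in (0, 1), got {self.p}")
        if self.variant in (RICH, POOR):
            if self.n is None or self.n < 1:
                raise ValueError("rational variants require integer n >= 1")
            # Zero-average constraint must hold exactly, not to tolerance.
            if self.p * self.r_plus + (1 - self.p) * self.r_minus != 0:
                raise ValueError("zero-average constraint violated")

    # -- lattice geometry used by the exact engine ---------------------

    @property
    def is_rational(self) -> bool:
        return self.variant in (RICH, POOR)

    @property
    def lattice_scale(self) -> int:
        """Denominator turning cumulative rewards into integer keys.

        Rich models produce values ``k = i - n*j`` (already integral,
        scale 1); poor models produce ``k = i - j/n`` (integral after
        multiplying by ``n``).
        """
        self._require_rational()
        return 1 if self.variant == RICH else int(self.n)  # type: ignore[arg-type]

    @property
    def lattice_up(self) -> int:
        """Integer key shift of a high reward (``r_plus * scale``)."""
        return self.lattice_scale

    @property
    def lattice_down(self) -> int:
        """Integer key shift of a low reward (``r_minus * scale``)."""
        self._require_rational()
        return -int(self.n) if self.variant == RICH else -1  # type: ignore[arg-type]

    def _require_rational(self) -> None:
        if not self.is_rational:
            raise ValueError(
                "generic-p models are only supported by the Monte-Carlo "
                "oracle, not by the exact value engine"
            )

    def to_config(self) -> dict:
        """Serializable description used in run metadata."""
        if self.is_rational:
            return {"variant": self.variant, "n": self.n}
        return {"variant": self.variant, "p_generic": float(self.p)}


def make_reward_model(variant: str, n_or_p: Union[int, float]) -> RewardModel:
    """Build a reward model from its variant and index (or probability).

    ``n_or_p`` is the integer rational index ``n`` for ``"rich"`` /
    ``"poor"``, or the real probability ``p`` for ``"generic"``.
    """
    if variant == RICH:
        n = _check_index(n_or_p)
        return RewardModel(RICH, Fraction(n, n + 1), Fraction(-n), n=n)
    if variant == POOR:
        n = _check_index(n_or_p)
        return RewardModel(POOR, Fraction(1, n + 1), Fraction(-1, n), n=n)
    if variant == GENERIC:
        p = float(n_or_p)
        if not (0.0 < p < 1.0):
            raise ValueError(f"generic p must lie in (0, 1), got {p}")
        return RewardModel(GENERIC, p, -p / (1.0 - p))
    raise ValueError(f"unknown variant {variant!r}")


def rich(n: int) -> RewardModel:
    """Rich environment, ``p = n/(n+1)``."""
    return make_reward_model(RICH, n)


def poor(n: int) -> RewardModel:
    """Poor environment, ``p = 1/(n+1)``."""
    return make_reward_model(POOR, n)


def _check_index(n_or_p: Union[int, float]) -> int:
    n = int(n_or_p)
    if n != n_or_p or n < 1:
        raise ValueError(f"rational variants require integer n >= 1, got {n_or_p}")
    return n


def nearest_rational(p: float, n_max: int = 999) -> tuple[RewardModel, float]:
    """Closest rational reward model to a real success probability.

    Scans the rich family ``n/(n+1)`` and the poor family ``1/(n+1)``
    for ``n = 1..n_max`` and returns the model whose ``p`` is nearest,
    together with the absolute approximation error.  The caller must
    decide explicitly whether the approximation is acceptable; nothing
    is substituted silently.
    """
    if not (0.0 < p < 1.0):
        raise ValueError(f"p must lie in (0, 1), got {p}")
    best: Optional[RewardModel] = None
    best_err = float("inf")
    for n in range(1, n_max + 1):
        for model in (rich(n), poor(n)):
            err = abs(float(model.p) - p)
            if err < best_err:
                best, best_err = model, err
    assert best is not None
    return best, best_err
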