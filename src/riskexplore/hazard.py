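"""Beta-Bernoulli noisy-or hazard beliefs over bout length.

The agent entertains a hypothetical predator whose chance of having detected
it grows with the number of consecutive turns ``tau`` it has spent at the
object.  Detection by turn ``tau`` is the union (a noisy-or) of independent
per-turn Bernoulli causes ``Z_j ~ Bernoulli(theta_j)``, each with a Beta
prior, so the cumulative hazard is

    h(tau) = 1 - prod_{j <= tau} (1 - E[theta_j]),      theta_1 = 0 fixed,

equivalently the stick-breaking recursion
``h(tau) = h(tau-1) + (1 - h(tau-1)) * mu_tau``, which makes the hazard
monotone non-decreasing in ``tau``.  ``theta_1 = 0`` codes the approach turn
itself: the first turn at the object carries no detection risk, so realizable
bouts last 2-4 turns.

There is no actual predator, hence every completed bout is a negative
observation (``X_tau = 0``) and the posterior has a closed conjugate form:
increment the ``b`` pseudocount of every cause ``j <= tau``.  Positive
(detection) observations have no tractable posterior and never occur here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

__all__ = [
    "MIN_TAU",
    "MAX_TAU",
    "BetaParam",
    "HazardBelief",
    "beta_from_mean_var",
    "hazard_predictive",
    "observe_safe_bout",
]

#: Bout-length support: the hazard has learnable causes for tau = 2, 3, 4.
MIN_TAU = 2
MAX_TAU = 4


@dataclass(frozen=True, slots=True)
class BetaParam:
    """Beta(a, b) pseudocounts for one per-turn detection cause theta_j."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Beta pseudocounts must be positive, got a={self.a}, b={self.b}")

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def var(self) -> float:
        n = self.a + self.b
        return self.a * self.b / (n * n * (n + 1.0))


def beta_from_mean_var(mu: float, v: float) -> BetaParam:
    """Moment-match a Beta distribution from its mean and variance.

    Solves ``a = -mu (mu^2 - mu + v) / v`` and
    ``b = (mu - 1)(mu^2 - mu + v) / v``.  The variance of a Beta with mean
    ``mu`` is bounded by ``mu - mu^2``; ``v`` must lie strictly inside
    ``(0, mu - mu^2)`` for the pseudocounts to be positive.
    """
    if not (0.0 < mu < 1.0):
        raise ValueError(f"mean must lie in (0, 1), got mu={mu}")
    bound = mu - mu * mu
    if not (0.0 < v < bound):
        raise ValueError(
            f"variance must satisfy 0 < v < mu - mu^2 = {bound:.6g}, got v={v}"
        )
    common = (mu * mu - mu + v) / v  # negative on the valid domain
    return BetaParam(a=-mu * common, b=(mu - 1.0) * common)


@dataclass(frozen=True, slots=True)
class HazardBelief:
    """Posterior over the noisy-or hazard causes theta_2, theta_3, theta_4.

    ``theta_1`` is the structural constant 0 and is not represented.  The
    belief is a value object: updates return new instances so that planner
    branches can hold divergent posteriors.
    """

    params: tuple[BetaParam, BetaParam, BetaParam]

    @classmethod
    def from_mean_var(
        cls, means: tuple[float, float, float], variances: tuple[float, float, float]
    ) -> "HazardBelief":
        return cls(tuple(beta_from_mean_var(m, v) for m, v in zip(means, variances)))

    def param(self, tau: int) -> BetaParam:
        if not MIN_TAU <= tau <= MAX_TAU:
            raise ValueError(f"tau must be in [{MIN_TAU}, {MAX_TAU}], got {tau}")
        return self.params[tau - MIN_TAU]

    def mean(self, tau: int) -> float:
        """Posterior mean of theta_tau; equals the per-turn conditional hazard."""
        if tau == 1:
            return 0.0
        return self.param(tau).mean

    def hazard(self, tau: int) -> float:
        """Posterior-predictive cumulative hazard h(tau) = P(detected by tau)."""
        if not 1 <= tau <= MAX_TAU:
            raise ValueError(f"tau must be in [1, {MAX_TAU}], got {tau}")
        surv = 1.0
        for j in range(MIN_TAU, tau + 1):
            surv *= 1.0 - self.param(j).mean
        return 1.0 - surv

    def observe_safe_bout(self, tau: int) -> "HazardBelief":
        """Condition on a completed bout of length tau with no detection.

        ``X_tau = 0`` implies all causes ``Z_j = 0`` for ``j <= tau``, so each
        corresponding ``b`` pseudocount increments by one.
        """
        if not MIN_TAU <= tau <= MAX_TAU:
            raise ValueError(f"bout length must be in [{MIN_TAU}, {MAX_TAU}], got {tau}")
        return HazardBelief(
            tuple(
                BetaParam(p.a, p.b + 1.0) if j <= tau else p
                for j, p in zip(range(MIN_TAU, MAX_TAU + 1), self.params)
            )
        )

    def observe_safe_turn(self, tau: int) -> "HazardBelief":
        """Condition on surviving the single turn tau (``Z_tau = 0``).

        Applying this for tau = 2..k reproduces :meth:`observe_safe_bout` at
        bout length k; it is the within-bout incremental form used along
        planner branches.
        """
        if not MIN_TAU <= tau <= MAX_TAU:
            raise ValueError(f"tau must be in [{MIN_TAU}, {MAX_TAU}], got {tau}")
        return HazardBelief(
            tuple(
                BetaParam(p.a, p.b + 1.0) if j == tau else p
                for j, p in zip(range(MIN_TAU, MAX_TAU + 1), self.params)
            )
        )

    # -- serialization -------------------------------------------------

    def to_json(self) -> str:
        return json.dumps(
            {str(tau): {"a": p.a, "b": p.b} for tau, p in zip(range(MIN_TAU, MAX_TAU + 1), self.params)}
        )

    @classmethod
    def from_json(cls, text: str) -> "HazardBelief":
        data = json.loads(text)
        return cls(
            tuple(BetaParam(data[str(tau)]["a"], data[str(tau)]["b"]) for tau in range(MIN_TAU, MAX_TAU + 1))
        )


def hazard_predictive(belief: HazardBelief, tau: int) -> float:
    """Functional form of :meth:`HazardBelief.hazard`."""
    return belief.hazard(tau)


def observe_safe_bout(belief: HazardBelief, tau: int) -> HazardBelief:
    """Functional form of :meth:`HazardBelief.observe_safe_bout`."""
    return belief.observe_safe_bout(tau)
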