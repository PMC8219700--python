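"""Hyperbolic discounting values, indifference points, and the
preference-uncertainty choice rule.

The package works throughout in natural-log discount-rate space
(``log k``, with ``k`` per day): empirically, discount rates are
approximately log-normally distributed across people, so beliefs,
priors and population distributions are Gaussian on ``log k``.

The choice rule is a *sampling* rule: on every trial the agent draws a
fresh ``log k`` from their Gaussian belief and then chooses
deterministically by comparing discounted values. Decision variability
therefore reflects uncertainty about one's own preference (the belief
width), not noise injected after evaluation as in a softmax. The
probability of choosing the delayed option has the probit closed form
implemented in :func:`p_choose_delayed`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.special import ndtr

__all__ = [
    "OfferPair",
    "DiscountBelief",
    "ChoiceRecord",
    "discounted_value",
    "indifference_logk",
    "p_choose_delayed",
    "simulate_choice",
]

IMMEDIATE = "immediate"
DELAYED = "delayed"


@dataclass(frozen=True)
class OfferPair:
    """A smaller-sooner vs larger-later monetary choice.

    The immediate amount is paid at delay zero; the delayed amount after
    ``delay_days`` days. Amounts are abstract currency units.
    """

    amount_now: float
    amount_delayed: float
    delay_days: float

    def __post_init__(self) -> None:
        if not (self.amount_now > 0):
            raise ValueError(f"amount_now must be > 0, got {self.amount_now}")
        if not (self.amount_delayed > self.amount_now):
            raise ValueError(
                "amount_delayed must exceed amount_now "
                f"({self.amount_delayed} <= {self.amount_now})"
            )
        if not (self.delay_days > 0):
            raise ValueError(f"delay_days must be > 0, got {self.delay_days}")


@dataclass(frozen=True)
class DiscountBelief:
    """Gaussian belief over the natural-log discount rate.

    ``sigma`` — the belief width — IS the preference-uncertainty
    parameter: wider beliefs produce more variable choices and, in the
    social model, larger shifts toward a partner.
    """

    mu: float
    sigma: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("belief mean must be finite")
        if not (self.sigma > 0):
            raise ValueError(f"belief sigma must be > 0, got {self.sigma}")


@dataclass
class ChoiceRecord:
    """One trial of the task: the offer, who it was decided for, and the
    option taken. ``feedback_correct`` is set only on trials decided on
    behalf of the partner when feedback was given (phases 2 and 3)."""

    trial_index: int
    phase: int
    agent: str  # "self" | "other"
    option_chosen: str  # "immediate" | "delayed"
    offer: OfferPair
    feedback_correct: Optional[bool] = None


def discounted_value(reward: float, delay_days: float, k: float) -> float:
    """Hyperbolic present value ``R / (1 + k * D)``.

    Parameters
    ----------
    reward : float
        Reward magnitude R (> 0, currency units).
    delay_days : float
        Delay D in days (>= 0).
    k : float
        Hyperbolic discount rate per day (>= 0).
    """
    if reward <= 0:
        raise ValueError(f"reward must be > 0, got {reward}")
    if delay_days < 0:
        raise ValueError(f"delay_days must be >= 0, got {delay_days}")
    if k < 0:
        raise ValueError(f"k must be >= 0, got {k}")
    return reward / (1.0 + k * delay_days)


def indifference_logk(pair: OfferPair) -> float:
    """Natural-log discount rate at which both options are worth the same.

    Solving ``amount_now = amount_delayed / (1 + k * D)`` gives
    ``k* = (amount_delayed / amount_now - 1) / D``. An agent whose log-k
    lies below ``ln k*`` prefers the delayed option.
    """
    ratio = pair.amount_delayed / pair.amount_now
    return math.log((ratio - 1.0) / pair.delay_days)


def p_choose_delayed(
    pair: OfferPair, belief: DiscountBelief, lapse: float = 0.0
) -> float:
    """Probability of taking the larger-later option under belief sampling.

    The agent samples ``log k ~ N(mu, sigma^2)`` and chooses the delayed
    option iff the sample falls below the pair's indifference log-k, so

    ``P(delayed) = (1 - lapse) * Phi((logk* - mu) / sigma) + lapse / 2``.

    ``lapse`` is a uniform lapse rate (default 0) that floors choice
    probabilities at ``lapse / 2``; it keeps likelihoods of degenerate
    all-one-option datasets finite during fitting.
    """
    if not (0.0 <= lapse < 1.0):
        raise ValueError(f"lapse must be in [0, 1), got {lapse}")
    z = (indifference_logk(pair) - belief.mu) / belief.sigma
    return (1.0 - lapse) * float(ndtr(z)) + lapse / 2.0


def simulate_choice(
    pair: OfferPair,
    belief: DiscountBelief,
    lapse: float = 0.0,
    rng: np.random.Generator | None = None,
    *,
    trial_index: int = 0,
    phase: int = 1,
    agent: str = "self",
) -> ChoiceRecord:
    """Draw one choice from the belief-sampling rule (Bernoulli at
    :func:`p_choose_delayed`); reproducible given the generator state."""
    if rng is None:
        rng = np.random.default_rng()
    p = p_choose_delayed(pair, belief, lapse)
    option = DELAYED if rng.random() < p else IMMEDIATE
    return ChoiceRecord(
        trial_index=trial_index,
        phase=phase,
        agent=agent,
        option_chosen=option,
        offer=pair,
    )
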