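"""Grid posterior over log-k and entropy-minimizing adaptive design.

During phase 1 the task maintains a discretized posterior over the
subject's log discount rate and, on adaptive trials, presents the
candidate offer pair whose outcome is expected to reduce the Shannon
entropy of that posterior the most. The same machinery is reused in
phase 2 to learn the partner's log-k from feedback.

The design likelihood is the probit choice rule of
:mod:`peershift.discounting` evaluated at each grid point with an
assumed choice-noise width ``noise_sigma`` (the subject's true
preference uncertainty is fitted later, not assumed here). With
``noise_sigma = 0`` the likelihood degenerates to a step function
(deterministic chooser), optionally smoothed by a lapse rate — the form
used when learning about the deterministic partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .discounting import DELAYED, IMMEDIATE, OfferPair, indifference_logk

__all__ = [
    "GridPosterior",
    "DesignConfig",
    "init_grid",
    "posterior_update",
    "entropy",
    "expected_posterior_entropy",
    "select_next_pair",
    "make_standard_set",
    "make_candidate_pool",
]

_NORM_TOL = 1e-10


@dataclass
class GridPosterior:
    """Probability distribution over discrete log-k support points."""

    grid: np.ndarray
    mass: np.ndarray

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        if self.grid.shape != self.mass.shape or self.grid.ndim != 1:
            raise ValueError("grid and mass must be 1-D arrays of equal length")
        if self.grid.size > 1 and not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.mass < 0):
            raise ValueError("posterior masses must be non-negative")
        if abs(self.mass.sum() - 1.0) > _NORM_TOL:
            raise ValueError("posterior mass must sum to 1")

    def mean(self) -> float:
        return float(self.grid @ self.mass)

    def var(self) -> float:
        m = self.mean()
        return float(((self.grid - m) ** 2) @ self.mass)

    def sd(self) -> float:
        return float(np.sqrt(self.var()))


@dataclass
class DesignConfig:
    """Geometry of the adaptive design.

    The defaults place 200 grid points uniformly on natural-log k in
    [ln 1e-4, ln 1] per day — spanning indifference horizons from under a
    week to multiple years — and a candidate pool whose indifference
    points tile that range at every delay in ``delays``.
    """

    logk_low: float = float(np.log(1e-4))
    logk_high: float = 0.0
    grid_size: int = 200
    delays: Sequence[float] = (7.0, 14.0, 30.0, 60.0, 120.0, 180.0, 365.0)
    n_pool_ratios: int = 40
    amount_now: float = 50.0
    noise_sigma: float = 1.0
    n_standard: int = 30
    standard_delays: Sequence[float] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not (self.logk_low < self.logk_high):
            raise ValueError("grid bounds must satisfy logk_low < logk_high")
        if self.grid_size < 1:
            raise ValueError("grid_size must be >= 1")
        if len(self.delays) == 0 or self.n_pool_ratios < 1:
            raise ValueError("candidate pool must be non-empty")
        if not self.standard_delays:
            self.standard_delays = tuple(self.delays)


def init_grid(config: DesignConfig) -> GridPosterior:
    """Uniform prior over the configured log-k grid."""
    grid = np.linspace(config.logk_low, config.logk_high, config.grid_size)
    mass = np.full(config.grid_size, 1.0 / config.grid_size)
    return GridPosterior(grid=grid, mass=mass)


def _delayed_likelihood(
    grid: np.ndarray, logk_star: float, noise_sigma: float, lapse: float
) -> np.ndarray:
    """P(choose delayed | log-k at each grid point) under the design
    likelihood; step function when noise_sigma = 0 (tie -> delayed)."""
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    if noise_sigma == 0.0:
        base = (grid <= logk_star).astype(float)
    else:
        base = ndtr((logk_star - grid) / noise_sigma)
    return (1.0 - lapse) * base + lapse / 2.0


def posterior_update(
    post: GridPosterior,
    pair: OfferPair,
    choice: str,
    noise_sigma: float,
    lapse: float = 0.0,
) -> GridPosterior:
    """Bayes update of the grid posterior after observing one choice."""
    if choice not in (IMMEDIATE, DELAYED):
        raise ValueError(f"choice must be 'immediate' or 'delayed', got {choice!r}")
    p_d = _delayed_likelihood(post.grid, indifference_logk(pair), noise_sigma, lapse)
    lik = p_d if choice == DELAYED else 1.0 - p_d
    unnorm = post.mass * lik
    total = unnorm.sum()
    if total <= 0:
        raise ValueError("zero total likelihood; use noise_sigma > 0 or lapse > 0")
    return GridPosterior(grid=post.grid, mass=unnorm / total)


def entropy(post: GridPosterior) -> float:
    """Shannon entropy in nats, with 0 * ln 0 = 0."""
    m = post.mass[post.mass > 0]
    return float(-(m @ np.log(m)))


def expected_posterior_entropy(
    post: GridPosterior,
    pair: OfferPair,
    noise_sigma: float,
    lapse: float = 0.0,
) -> float:
    """Expected entropy after presenting ``pair``, averaging over the two
    possible choices under the current posterior predictive."""
    p_d = _delayed_likelihood(post.grid, indifference_logk(pair), noise_sigma, lapse)
    out = 0.0
    for lik in (p_d, 1.0 - p_d):
        p_choice = float(post.mass @ lik)
        if p_choice <= 0:
            continue
        branch = GridPosterior(grid=post.grid, mass=post.mass * lik / p_choice)
        out += p_choice * entropy(branch)
    return out


def select_next_pair(
    post: GridPosterior,
    pool: Sequence[OfferPair],
    noise_sigma: float = 1.0,
    lapse: float = 0.0,
) -> OfferPair:
    """The pool member minimizing expected posterior entropy.

    Ties break to the lowest pool index. The computation is vectorized
    over the pool (one likelihood matrix, pool x grid).
    """
    if len(pool) == 0:
        raise ValueError("candidate pool is empty")
    logk_stars = np.array([indifference_logk(p) for p in pool])
    if noise_sigma == 0.0:
        base = (post.grid[None, :] <= logk_stars[:, None]).astype(float)
    else:
        base = ndtr((logk_stars[:, None] - post.grid[None, :]) / noise_sigma)
    lik_d = (1.0 - lapse) * base + lapse / 2.0

    scores = np.zeros(len(pool))
    for lik in (lik_d, 1.0 - lik_d):
        joint = lik * post.mass[None, :]
        p_choice = joint.sum(axis=1)
        ok = p_choice > 0
        branch = joint[ok] / p_choice[ok, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(branch > 0, branch * np.log(branch), 0.0)
        scores[ok] += p_choice[ok] * (-plogp.sum(axis=1))
    return pool[int(np.argmin(scores))]


def _pair_from_logk_star(
    logk_star: float, delay: float, amount_now: float
) -> OfferPair:
    """Offer pair whose indifference log-k equals ``logk_star`` at the
    given delay (amount_delayed = amount_now * (1 + k* * delay))."""
    k_star = float(np.exp(logk_star))
    return OfferPair(
        amount_now=round(amount_now, 2),
        amount_delayed=round(amount_now * (1.0 + k_star * delay), 2),
        delay_days=delay,
    )


def make_standard_set(config: DesignConfig) -> list[OfferPair]:
    """The fixed 30-pair set: indifference log-k values evenly spaced
    across the grid bounds, delays cycling through the configured delay
    set. Deterministic given the config."""
    # keep targets strictly inside the bounds so rounding cannot escape them
    span = config.logk_high - config.logk_low
    targets = np.linspace(
        config.logk_low + 0.01 * span,
        config.logk_high - 0.01 * span,
        config.n_standard,
    )
    delays = list(config.standard_delays)
    return [
        _pair_from_logk_star(t, delays[i % len(delays)], config.amount_now)
        for i, t in enumerate(targets)
    ]


def make_candidate_pool(config: DesignConfig) -> list[OfferPair]:
    """Factorial candidate pool: every delay crossed with amount ratios
    log-spaced so the pool's indifference points tile the grid bounds."""
    targets = np.linspace(config.logk_low, config.logk_high, config.n_pool_ratios)
    return [
        _pair_from_logk_star(t, d, config.amount_now)
        for d in config.delays
        for t in targets
    ]
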