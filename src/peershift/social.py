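"""Bayesian informational-conformity model and the three-phase session
simulator.

The task has three phases:

1. *Self* — 60 intertemporal choices for oneself: 30 from a fixed
   standard set interleaved with 30 chosen adaptively to shrink the
   entropy of a grid posterior over the subject's log-k.
2. *Learning about the other* — the subject chooses on behalf of a
   partner and receives correct/incorrect feedback, until 8 of the most
   recent 10 answers are correct (minimum 20 trials) or 60 trials
   elapse. The partner's log-k is displaced exactly one population SD
   from the subject's phase-1 estimate, toward the population mean with
   probability 2/3 and away from it with probability 1/3.
3. *Post* — alternating self/other mini-blocks of 10 trials; the self
   trials measure how far the subject's preference has shifted.

The conformity mechanism is informational ("copy when uncertain"): the
subject and partner are modelled as draws from a shared Gaussian
reference distribution ``N(m, sigma_ref^2)`` around a latent common mean
``m`` with a flat hyperprior. Learning the partner's log-k is then
evidence about one's own, and the posterior over the subject's log-k
shifts toward the partner by a weight that grows with the subject's own
preference uncertainty and falls with ``sigma_ref`` (the "relevance of
the other": a wide reference distribution makes the partner
uninformative). See :func:`social_update` for the closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Optional, Protocol

import numpy as np

from .adaptive import (
    DesignConfig,
    GridPosterior,
    init_grid,
    make_candidate_pool,
    make_standard_set,
    posterior_update,
    select_next_pair,
)
from .discounting import (
    DELAYED,
    IMMEDIATE,
    ChoiceRecord,
    DiscountBelief,
    OfferPair,
    indifference_logk,
    simulate_choice,
)

if TYPE_CHECKING:  # pragma: no cover
    from .cohort import SubjectParams

__all__ = [
    "ReferenceModel",
    "PartnerSpec",
    "TaskConfig",
    "SessionRecord",
    "PosteriorMeanLearner",
    "assign_partner",
    "score_other_choice",
    "run_phase2",
    "social_update",
    "simulate_session",
]

TOWARD = "toward_mean"
AWAY = "away_from_mean"


@dataclass(frozen=True)
class ReferenceModel:
    """Shared reference distribution coupling self and partner log-k.

    ``sigma_ref`` is its width — the 'relevance of the other'. The
    hyperprior on the latent common mean is flat (improper); a proper
    population hyperprior would add shrinkage toward the population mean
    and is deliberately not the default.
    """

    sigma_ref: float

    def __post_init__(self) -> None:
        if not (self.sigma_ref > 0):
            raise ValueError(f"sigma_ref must be > 0, got {self.sigma_ref}")


@dataclass(frozen=True)
class PartnerSpec:
    """The computerised partner: a deterministic discounter at
    ``logk_other``, displaced one population SD from the subject's
    phase-1 estimate in the recorded direction."""

    logk_other: float
    direction: str  # "toward_mean" | "away_from_mean"


@dataclass
class TaskConfig:
    """Session structure and the population parameters used for partner
    assignment. Defaults give the standard session geometry: 60
    phase-1 trials (30 fixed + 30 adaptive), a 20-trial floor and
    60-trial ceiling with an 8-of-10 criterion in phase 2, and phase-3
    mini-blocks of 10 trials (three per agent, self first)."""

    design: DesignConfig = field(default_factory=DesignConfig)
    n_phase1: int = 60
    phase2_floor: int = 20
    phase2_ceiling: int = 60
    phase2_window: int = 10
    phase2_needed: int = 8
    phase3_block: int = 10
    phase3_blocks_per_agent: int = 3
    lapse: float = 0.0
    learner_lapse: float = 0.05
    population_mean: float = float(np.log(0.01))
    population_sd: float = 1.5


@dataclass
class SessionRecord:
    """Complete trial-level log of one subject x timepoint."""

    subject_id: str
    timepoint: str  # "T1" | "short_followup" | "T2"
    choices: list[ChoiceRecord]
    partner: PartnerSpec
    logk_hat_phase1: float
    other_posterior_mean: float
    other_posterior_var: float
    phase2_stop_trial: int
    seed: Optional[int] = None
    params: Optional["SubjectParams"] = None
    sigma_pref_session: Optional[float] = None  # generative width at this timepoint

    def phase_choices(self, phase: int, agent: str | None = None) -> list[ChoiceRecord]:
        return [
            c
            for c in self.choices
            if c.phase == phase and (agent is None or c.agent == agent)
        ]


def assign_partner(
    logk_self_hat: float,
    population_mean: float,
    population_sd: float,
    rng: np.random.Generator,
) -> PartnerSpec:
    """Displace the partner's log-k one population SD from the subject's
    estimate: toward the population mean with probability 2/3, away with
    probability 1/3. A subject sitting exactly at the population mean
    has no 'toward' direction; the displacement sign is then random and
    the drawn direction label is kept."""
    if not (population_sd > 0):
        raise ValueError("population_sd must be > 0")
    if not (math.isfinite(logk_self_hat) and math.isfinite(population_mean)):
        raise ValueError("inputs must be finite")
    toward = rng.random() < 2.0 / 3.0
    gap = population_mean - logk_self_hat
    if gap == 0.0:
        sign = 1.0 if rng.random() < 0.5 else -1.0
    else:
        sign = math.copysign(1.0, gap)
    if not toward:
        sign = -sign
    return PartnerSpec(
        logk_other=logk_self_hat + sign * population_sd,
        direction=TOWARD if toward else AWAY,
    )


def score_other_choice(choice: str, pair: OfferPair, logk_other: float) -> bool:
    """Whether ``choice`` matches a simulation of the partner: the
    partner deterministically maximizes discounted value at their log-k,
    taking the delayed option at exact indifference."""
    partner_choice = DELAYED if logk_other <= indifference_logk(pair) else IMMEDIATE
    return choice == partner_choice


class Phase2Learner(Protocol):  # pragma: no cover - typing only
    posterior: GridPosterior

    def propose_pair(self) -> OfferPair: ...
    def choose_for_other(self, pair: OfferPair) -> str: ...
    def observe(self, pair: OfferPair, partner_choice: str) -> None: ...


class PosteriorMeanLearner:
    """Learner used in phases 2 and 3 'other' trials.

    Chooses on the partner's behalf by maximizing value at the current
    posterior mean of the partner's log-k, proposes the next offer by
    expected-entropy minimization, and updates its grid posterior from
    the partner's (feedback-revealed) choice under a deterministic-other
    likelihood smoothed by a small lapse (default 0.05) so that no
    feedback sequence has zero likelihood.
    """

    def __init__(self, design: DesignConfig, lapse: float = 0.05) -> None:
        self.posterior = init_grid(design)
        self.pool = make_candidate_pool(design)
        self.lapse = lapse

    def propose_pair(self) -> OfferPair:
        return select_next_pair(self.posterior, self.pool, noise_sigma=0.0, lapse=self.lapse)

    def choose_for_other(self, pair: OfferPair) -> str:
        return DELAYED if self.posterior.mean() <= indifference_logk(pair) else IMMEDIATE

    def observe(self, pair: OfferPair, partner_choice: str) -> None:
        self.posterior = posterior_update(
            self.posterior, pair, partner_choice, noise_sigma=0.0, lapse=self.lapse
        )


def run_phase2(
    learner: Phase2Learner,
    partner: PartnerSpec,
    config: TaskConfig,
    *,
    phase: int = 2,
    start_index: int = 0,
) -> tuple[list[ChoiceRecord], GridPosterior]:
    """Learning-about-the-other loop with the 8-of-10 stopping rule.

    Trials run until the first trial ``t >= phase2_floor`` at which at
    least ``phase2_needed`` of the most recent ``phase2_window`` answers
    were correct, or until ``phase2_ceiling`` trials have been shown.
    Returns the choice records and the learner's final posterior over
    the partner's log-k.
    """
    choices: list[ChoiceRecord] = []
    correct_flags: list[bool] = []
    for t in range(1, config.phase2_ceiling + 1):
        pair = learner.propose_pair()
        choice = learner.choose_for_other(pair)
        correct = score_other_choice(choice, pair, partner.logk_other)
        partner_choice = choice if correct else (IMMEDIATE if choice == DELAYED else DELAYED)
        learner.observe(pair, partner_choice)
        choices.append(
            ChoiceRecord(
                trial_index=start_index + t - 1,
                phase=phase,
                agent="other",
                option_chosen=choice,
                offer=pair,
                feedback_correct=correct,
            )
        )
        correct_flags.append(correct)
        window = correct_flags[-config.phase2_window :]
        if t >= config.phase2_floor and sum(window) >= config.phase2_needed:
            break
    return choices, learner.posterior


def social_update(
    belief_self: DiscountBelief,
    mu_other: float,
    var_other: float,
    ref: ReferenceModel,
) -> DiscountBelief:
    """Shift one's preference belief after learning about the partner.

    Model: ``k_self ~ N(m, sigma_ref^2)`` and ``k_other ~ N(m,
    sigma_ref^2)`` share a latent mean ``m`` with a flat hyperprior; the
    phase-2 posterior over the partner is ``N(mu_other, var_other)``.
    Marginalizing ``m`` and ``k_other`` gives the predictive for one's
    own log-k from social evidence alone,

    ``k_self | d_O ~ N(mu_other, var_other + 2 sigma_ref^2)``,

    which combines with the self belief ``N(mu, sigma^2)`` by precision
    weighting. The posterior mean is ``mu + w (mu_other - mu)`` with
    shift weight

    ``w = sigma^2 / (sigma^2 + 2 sigma_ref^2 + var_other)``,

    so 0 <= w < 1 always: more preference uncertainty means a larger
    shift, a less relevant (wider-reference) or less well-learned
    partner a smaller one. The posterior variance is the harmonic
    combination of the two variances and never exceeds ``sigma^2``.
    """
    if var_other < 0:
        raise ValueError(f"var_other must be >= 0, got {var_other}")
    v_self = belief_self.sigma**2
    v_social = var_other + 2.0 * ref.sigma_ref**2
    w = v_self / (v_self + v_social)
    mean = belief_self.mu + w * (mu_other - belief_self.mu)
    var = v_self * v_social / (v_self + v_social)
    return DiscountBelief(mu=mean, sigma=math.sqrt(var))


def _phase1(
    belief: DiscountBelief,
    config: TaskConfig,
    rng: np.random.Generator,
) -> tuple[list[ChoiceRecord], GridPosterior]:
    """Fixed/adaptive interleaved self trials; even indices come from the
    standard set, odd indices from the entropy-minimizing selector."""
    standard = make_standard_set(config.design)
    pool = make_candidate_pool(config.design)
    post = init_grid(config.design)
    noise = config.design.noise_sigma
    choices: list[ChoiceRecord] = []
    for t in range(config.n_phase1):
        if t % 2 == 0:
            pair = standard[(t // 2) % len(standard)]
        else:
            pair = select_next_pair(post, pool, noise_sigma=noise)
        rec = simulate_choice(
            pair, belief, config.lapse, rng, trial_index=t, phase=1, agent="self"
        )
        post = posterior_update(post, pair, rec.option_chosen, noise_sigma=noise)
        choices.append(rec)
    return choices, post


def simulate_session(
    params: "SubjectParams",
    config: TaskConfig | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    timepoint: str = "T1",
    sigma_pref: float | None = None,
) -> SessionRecord:
    """Simulate one complete three-phase session for one subject.

    The subject's generative belief is ``N(mu_logk_true,
    sigma_pref^2)``; the phase-1 posterior mean seeds partner
    assignment; the preference belief is updated once, after phase 2,
    via :func:`social_update` with the final partner posterior; phase-3
    self choices are drawn from the updated belief. Fully reproducible
    given the seed.

    ``sigma_pref`` overrides the baseline uncertainty in
    ``params`` (used for follow-up sessions where uncertainty has
    declined).
    """
    if config is None:
        config = TaskConfig()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)

    sp = float(params.sigma_pref_true if sigma_pref is None else sigma_pref)
    belief1 = DiscountBelief(mu=params.mu_logk_true, sigma=sp)

    choices, post_self = _phase1(belief1, config, rng)
    logk_hat1 = post_self.mean()

    partner = assign_partner(
        logk_hat1, config.population_mean, config.population_sd, rng
    )

    learner = PosteriorMeanLearner(config.design, lapse=config.learner_lapse)
    p2_choices, other_post = run_phase2(
        learner, partner, config, phase=2, start_index=len(choices)
    )
    choices.extend(p2_choices)
    mu_o, var_o = other_post.mean(), other_post.var()

    belief3 = social_update(
        belief1, mu_o, var_o, ReferenceModel(sigma_ref=params.sigma_ref_true)
    )

    standard = make_standard_set(config.design)
    idx = len(choices)
    self_cursor = 0
    for _ in range(config.phase3_blocks_per_agent):
        for _ in range(config.phase3_block):  # self block
            pair = standard[self_cursor % len(standard)]
            self_cursor += 1
            choices.append(
                simulate_choice(
                    pair, belief3, config.lapse, rng,
                    trial_index=idx, phase=3, agent="self",
                )
            )
            idx += 1
        for _ in range(config.phase3_block):  # other block, feedback continues
            pair = learner.propose_pair()
            choice = learner.choose_for_other(pair)
            correct = score_other_choice(choice, pair, partner.logk_other)
            partner_choice = (
                choice if correct else (IMMEDIATE if choice == DELAYED else DELAYED)
            )
            learner.observe(pair, partner_choice)
            choices.append(
                ChoiceRecord(
                    trial_index=idx, phase=3, agent="other",
                    option_chosen=choice, offer=pair, feedback_correct=correct,
                )
            )
            idx += 1

    return SessionRecord(
        subject_id=str(params.subject_id),
        timepoint=timepoint,
        choices=choices,
        partner=partner,
        logk_hat_phase1=logk_hat1,
        other_posterior_mean=mu_o,
        other_posterior_var=var_o,
        phase2_stop_trial=len(p2_choices),
        seed=seed,
        params=params,
        sigma_pref_session=sp,
    )
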