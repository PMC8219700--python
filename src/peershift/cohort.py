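"""Synthetic developmental cohort generator.

Emulates the statistical structure the developmental analyses assume,
with no external data:

* discount rates log-normally distributed across subjects (Gaussian on
  natural-log k);
* preference uncertainty declining cross-sectionally with age, through
  a softplus link on a linear-in-age predictor plus subject-level
  noise (the softplus keeps every width strictly positive);
* a longitudinal within-person decline of preference uncertainty whose
  rate is steeper for younger baseline ages;
* follow-up intervals drawn from a truncated normal centred on 1.48
  years, and an optional retest subsample with a third, ~6-month,
  session.

Population magnitudes are package defaults chosen to be typical of the
hyperbolic-discounting literature and to give desk-scale cohorts clear
qualitative structure; they are config-exposed, not estimates from any
particular study.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .social import SessionRecord, TaskConfig, simulate_session

__all__ = [
    "SubjectParams",
    "CohortSpec",
    "generate_cohort",
    "sigma_pref_at",
    "simulate_longitudinal",
]

T1 = "T1"
SHORT = "short_followup"
T2 = "T2"


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one synthetic subject."""

    subject_id: str
    age_baseline: float
    mu_logk_true: float
    sigma_pref_true: float
    sigma_ref_true: float
    followup_interval: float  # years between T1 and T2
    retest: bool = False  # member of the 3-timepoint subsample


@dataclass
class CohortSpec:
    """Generative description of the synthetic cohort.

    Preference uncertainty is ``softplus(a - b * age + noise)`` with
    ``a = uncertainty_intercept``, ``b = uncertainty_age_slope``; the
    defaults put the expected width near 1.2 at age 14 and 0.65 at age
    25. The longitudinal decline acts on the softplus argument at rate
    ``decline_base + decline_age_slope * (age_ceiling - age_baseline)``
    per year, so younger subjects decline faster and every subject's
    width shrinks between sessions.
    """

    n_subjects: int = 300
    age_low: float = 14.10
    age_high: float = 24.99
    population_logk_mean: float = float(np.log(0.01))
    population_logk_sd: float = 1.5
    uncertainty_intercept: float = 2.2
    uncertainty_age_slope: float = 0.095
    uncertainty_noise_sd: float = 0.3
    sigma_ref_logmean: float = float(np.log(0.7))
    sigma_ref_logsd: float = 0.3
    decline_base: float = 0.08  # per year, softplus-argument units
    decline_age_slope: float = 0.03  # extra per year below age_ceiling
    age_ceiling: float = 25.0
    followup_mean: float = 1.48
    followup_sd: float = 0.30
    followup_bounds: tuple[float, float] = (0.98, 2.62)
    short_followup_interval: float = 0.5
    retest_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not (self.age_low < self.age_high):
            raise ValueError("age range must be non-empty")
        if self.uncertainty_age_slope <= 0:
            raise ValueError("uncertainty_age_slope must be > 0 (decline with age)")
        if self.decline_base < 0 or self.decline_age_slope < 0:
            raise ValueError("decline rates must be >= 0")
        lo = self.uncertainty_intercept - self.uncertainty_age_slope * self.age_high
        # softplus is positive everywhere, but an argument this negative
        # signals a spec whose widths underflow to ~0 over the age range
        if lo < -20:
            raise ValueError("uncertainty mapping collapses to zero over age range")


def _softplus(x: float) -> float:
    return float(np.logaddexp(0.0, x))


def _softplus_inv(y: float) -> float:
    if y <= 0:
        raise ValueError("softplus output must be > 0")
    return y + math.log(-math.expm1(-y))


def _decline_rate(age_baseline: float, spec: CohortSpec) -> float:
    return spec.decline_base + spec.decline_age_slope * max(
        0.0, spec.age_ceiling - age_baseline
    )


def sigma_pref_at(
    params: SubjectParams, years_since_baseline: float, spec: CohortSpec
) -> float:
    """Preference uncertainty at a follow-up session: the baseline
    softplus argument minus the subject's age-dependent decline rate
    times elapsed years."""
    if years_since_baseline < 0:
        raise ValueError("years_since_baseline must be >= 0")
    eta1 = _softplus_inv(params.sigma_pref_true)
    return _softplus(eta1 - _decline_rate(params.age_baseline, spec) * years_since_baseline)


def generate_cohort(spec: CohortSpec, seed: int) -> list[SubjectParams]:
    """Draw a cohort of :class:`SubjectParams`; reproducible given seed."""
    rng = np.random.default_rng(seed)
    ages = rng.uniform(spec.age_low, spec.age_high, spec.n_subjects)
    mus = rng.normal(
        spec.population_logk_mean, spec.population_logk_sd, spec.n_subjects
    )
    etas = (
        spec.uncertainty_intercept
        - spec.uncertainty_age_slope * ages
        + rng.normal(0.0, spec.uncertainty_noise_sd, spec.n_subjects)
    )
    sigma_refs = rng.lognormal(
        spec.sigma_ref_logmean, spec.sigma_ref_logsd, spec.n_subjects
    )
    lo, hi = spec.followup_bounds
    intervals = np.clip(
        rng.normal(spec.followup_mean, spec.followup_sd, spec.n_subjects), lo, hi
    )
    n_retest = int(round(spec.retest_fraction * spec.n_subjects))
    retest_ids = set(rng.choice(spec.n_subjects, size=n_retest, replace=False))
    width = len(str(spec.n_subjects))
    return [
        SubjectParams(
            subject_id=f"S{i:0{width}d}",
            age_baseline=float(ages[i]),
            mu_logk_true=float(mus[i]),
            sigma_pref_true=_softplus(float(etas[i])),
            sigma_ref_true=float(sigma_refs[i]),
            followup_interval=float(intervals[i]),
            retest=i in retest_ids,
        )
        for i in range(spec.n_subjects)
    ]


def simulate_longitudinal(
    cohort: Sequence[SubjectParams],
    config: TaskConfig | None = None,
    seed: int = 0,
    spec: CohortSpec | None = None,
) -> list[SessionRecord]:
    """Simulate every subject at every timepoint.

    Each subject plays the full three-phase task at T1 and again at T2
    (``followup_interval`` years later, with preference uncertainty
    declined per the spec); subjects flagged as retest members get an
    additional short-follow-up session in between. The partner is
    re-assigned at every timepoint from that timepoint's phase-1
    estimate. Session seeds are spawned deterministically from ``seed``.
    """
    spec = spec or CohortSpec()
    config = config or TaskConfig()
    ss = np.random.SeedSequence(seed)
    sessions: list[SessionRecord] = []
    for params in cohort:
        points: list[tuple[str, float]] = [(T1, 0.0)]
        if params.retest:
            points.append((SHORT, spec.short_followup_interval))
        points.append((T2, params.followup_interval))
        for tp, dt in points:
            child = np.random.default_rng(ss.spawn(1)[0])
            sessions.append(
                simulate_session(
                    params,
                    config,
                    child,
                    timepoint=tp,
                    sigma_pref=sigma_pref_at(params, dt, spec),
                )
            )
    return sessions
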