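"""Per-subject MAP estimation of discounting parameters and social-shift
scores.

Each phase of self choices is fitted with the belief-sampling probit
likelihood on a 2-D (mu, sigma) grid, refined by Nelder-Mead from the
grid optimum. Weak priors — ``mu ~ N(population mean, 2 * population
SD)`` and ``sigma ~ logNormal(0, 1)`` — regularize degenerate subjects
whose choices are all one option; they are switchable off for pure MLE.
The relevance-of-the-other width ``sigma_ref`` is estimated afterwards
by maximizing the likelihood of phase-3 self choices under the belief
predicted by the social update, searched on a log-spaced grid.

Fitting is deterministic given the data: no randomness enters the grid
search or the local refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize, minimize_scalar
from scipy.special import ndtr

from .discounting import DELAYED, ChoiceRecord, DiscountBelief, indifference_logk
from .social import PartnerSpec, ReferenceModel, SessionRecord, social_update

__all__ = [
    "FitConfig",
    "PhaseFit",
    "FitResult",
    "ShiftResult",
    "fit_phase",
    "fit_social",
    "compute_shift",
    "fit_sessions",
]

_P_FLOOR = 1e-12


@dataclass
class FitConfig:
    """Search geometry and priors for per-phase MAP fitting."""

    mu_low: float = float(np.log(1e-4))
    mu_high: float = 0.0
    n_mu: int = 60
    sigma_low: float = 0.05
    sigma_high: float = 5.0
    n_sigma: int = 40
    use_prior: bool = True
    prior_mu_mean: float = float(np.log(0.01))
    prior_mu_sd: float = 3.0  # 2 x population SD
    prior_sigma_logmean: float = 0.0
    prior_sigma_logsd: float = 1.0
    lapse: float = 0.0
    # sigma_ref search (log-spaced)
    sigma_ref_low: float = 0.05
    sigma_ref_high: float = 10.0
    n_sigma_ref: int = 60
    min_trials: int = 10


@dataclass
class PhaseFit:
    """MAP estimate for one phase of self choices."""

    mu: float
    sigma: float
    loglik: float
    boundary: bool
    n_trials: int


@dataclass
class FitResult:
    """Complete per-session parameter estimates."""

    subject_id: str
    timepoint: str
    logk_phase1: float
    sigma_pref_hat: float
    logk_phase3: float
    sigma_phase3_hat: float
    loglik_phase1: float
    loglik_phase3: float
    sigma_ref_hat: Optional[float] = None
    loglik_social: Optional[float] = None
    boundary_phase1: bool = False
    boundary_phase3: bool = False
    sigma_ref_flag: bool = False


@dataclass
class ShiftResult:
    """Social-shift scores derived from the phase-1 and phase-3 fits.

    ``shift = logk_phase3 - logk_phase1``; positive values mean the
    subject became more impatient. ``relative_shift = shift /
    logk_phase1`` inherits the sign of the (typically negative)
    denominator: a shift of +1 from logk1 = -5 gives -0.2.
    ``signed_toward_shift`` re-signs the shift so that positive always
    means movement toward the partner; it is the susceptibility measure
    used in the developmental analyses.
    """

    shift: float
    relative_shift: Optional[float]
    toward_partner: Optional[bool]
    signed_toward_shift: Optional[float]


def _choice_arrays(choices: Sequence[ChoiceRecord]) -> tuple[np.ndarray, np.ndarray]:
    logk_star = np.array([indifference_logk(c.offer) for c in choices])
    y = np.array([1.0 if c.option_chosen == DELAYED else 0.0 for c in choices])
    return logk_star, y


def _loglik_grid(
    logk_star: np.ndarray,
    y: np.ndarray,
    mu: np.ndarray,
    sigma: np.ndarray,
    lapse: float,
) -> np.ndarray:
    """Log-likelihood on the full mu x sigma grid (vectorized)."""
    z = (logk_star[None, None, :] - mu[:, None, None]) / sigma[None, :, None]
    p = (1.0 - lapse) * ndtr(z) + lapse / 2.0
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return (y * np.log(p) + (1.0 - y) * np.log1p(-p)).sum(axis=2)


def _loglik_point(
    logk_star: np.ndarray, y: np.ndarray, mu: float, sigma: float, lapse: float
) -> float:
    p = (1.0 - lapse) * ndtr((logk_star - mu) / sigma) + lapse / 2.0
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return float(y @ np.log(p) + (1.0 - y) @ np.log1p(-p))


def _log_prior(mu: np.ndarray, sigma: np.ndarray, cfg: FitConfig) -> np.ndarray:
    lp_mu = -0.5 * ((mu - cfg.prior_mu_mean) / cfg.prior_mu_sd) ** 2
    ls = np.log(sigma)
    lp_sigma = -0.5 * ((ls - cfg.prior_sigma_logmean) / cfg.prior_sigma_logsd) ** 2 - ls
    return lp_mu[:, None] + lp_sigma[None, :]


def fit_phase(
    choices: Sequence[ChoiceRecord], config: FitConfig | None = None
) -> PhaseFit:
    """MAP (mu, sigma) for one phase of self choices.

    Grid search over ``n_mu x n_sigma`` points followed by Nelder-Mead
    refinement in (mu, log sigma). Datasets with fewer than
    ``min_trials`` choices or only one option type are fitted anyway but
    flagged as boundary estimates; refinement is skipped when the grid
    optimum sits on a search edge so degenerate data stay pinned there.
    """
    cfg = config or FitConfig()
    if len(choices) == 0:
        raise ValueError("cannot fit an empty choice list")
    logk_star, y = _choice_arrays(choices)

    mu_grid = np.linspace(cfg.mu_low, cfg.mu_high, cfg.n_mu)
    sigma_grid = np.geomspace(cfg.sigma_low, cfg.sigma_high, cfg.n_sigma)
    obj = _loglik_grid(logk_star, y, mu_grid, sigma_grid, cfg.lapse)
    if cfg.use_prior:
        obj = obj + _log_prior(mu_grid, sigma_grid, cfg)

    i, j = np.unravel_index(int(np.argmax(obj)), obj.shape)
    on_edge = i in (0, cfg.n_mu - 1) or j in (0, cfg.n_sigma - 1)
    degenerate = len(choices) < cfg.min_trials or y.min() == y.max()
    mu_hat, sigma_hat = float(mu_grid[i]), float(sigma_grid[j])

    if not on_edge:

        def neg_post(theta: np.ndarray) -> float:
            m, ls = theta
            s = math.exp(ls)
            val = _loglik_point(logk_star, y, m, s, cfg.lapse)
            if cfg.use_prior:
                val += -0.5 * ((m - cfg.prior_mu_mean) / cfg.prior_mu_sd) ** 2
                val += (
                    -0.5 * ((ls - cfg.prior_sigma_logmean) / cfg.prior_sigma_logsd) ** 2
                    - ls
                )
            return -val

        res = minimize(
            neg_post,
            x0=np.array([mu_hat, math.log(sigma_hat)]),
            method="Nelder-Mead",
            options={"xatol": 1e-4, "fatol": 1e-6, "maxiter": 400},
        )
        if res.success or res.status == 2:  # accept maxiter terminations too
            mu_hat = float(res.x[0])
            sigma_hat = float(math.exp(res.x[1]))

    return PhaseFit(
        mu=mu_hat,
        sigma=sigma_hat,
        loglik=_loglik_point(logk_star, y, mu_hat, sigma_hat, cfg.lapse),
        boundary=bool(on_edge or degenerate),
        n_trials=len(choices),
    )


def fit_social(
    session: SessionRecord,
    config: FitConfig | None = None,
    *,
    phase1: PhaseFit | None = None,
) -> FitResult:
    """Full per-session fit: phase-1 and phase-3 (mu, sigma) plus the
    relevance-of-the-other width ``sigma_ref``.

    ``sigma_ref`` is chosen to maximize the likelihood of phase-3 self
    choices under the belief predicted by the social update applied to
    the phase-1 fit and the phase-2 partner posterior. Unidentifiable
    cases — partner estimate indistinguishable from the subject's own,
    or a near-zero fitted preference uncertainty (shift weight ~ 0 for
    every ``sigma_ref``) — and grid-edge optima set ``sigma_ref_flag``.
    """
    cfg = config or FitConfig()
    p1 = phase1 or fit_phase(session.phase_choices(1, agent="self"), cfg)
    p3_choices = session.phase_choices(3, agent="self")
    p3 = fit_phase(p3_choices, cfg)

    logk_star, y = _choice_arrays(p3_choices)
    mu_o, var_o = session.other_posterior_mean, session.other_posterior_var
    belief1 = DiscountBelief(mu=p1.mu, sigma=max(p1.sigma, 1e-6))

    def social_loglik(sigma_ref: float) -> float:
        b = social_update(belief1, mu_o, var_o, ReferenceModel(sigma_ref=sigma_ref))
        return _loglik_point(logk_star, y, b.mu, b.sigma, cfg.lapse)

    ref_grid = np.geomspace(cfg.sigma_ref_low, cfg.sigma_ref_high, cfg.n_sigma_ref)
    lls = np.array([social_loglik(s) for s in ref_grid])
    j = int(np.argmax(lls))
    sigma_ref_hat = float(ref_grid[j])
    flat = float(lls.max() - lls.min()) < 1e-6
    unidentifiable = abs(mu_o - p1.mu) < 0.1 or p1.sigma < 0.05
    on_edge = j in (0, cfg.n_sigma_ref - 1)
    if not (on_edge or flat):
        res = minimize_scalar(
            lambda ls: -social_loglik(math.exp(ls)),
            bounds=(math.log(cfg.sigma_ref_low), math.log(cfg.sigma_ref_high)),
            method="bounded",
            options={"xatol": 1e-5},
        )
        if res.success and -res.fun >= lls[j]:
            sigma_ref_hat = float(math.exp(res.x))

    return FitResult(
        subject_id=session.subject_id,
        timepoint=session.timepoint,
        logk_phase1=p1.mu,
        sigma_pref_hat=p1.sigma,
        logk_phase3=p3.mu,
        sigma_phase3_hat=p3.sigma,
        loglik_phase1=p1.loglik,
        loglik_phase3=p3.loglik,
        sigma_ref_hat=sigma_ref_hat,
        loglik_social=social_loglik(sigma_ref_hat),
        boundary_phase1=p1.boundary,
        boundary_phase3=p3.boundary,
        sigma_ref_flag=bool(on_edge or flat or unidentifiable),
    )


def compute_shift(fit: FitResult, partner: PartnerSpec) -> ShiftResult:
    """Social-shift scores from a session's fitted log-k values."""
    shift = fit.logk_phase3 - fit.logk_phase1
    relative = shift / fit.logk_phase1 if fit.logk_phase1 != 0.0 else None
    gap = partner.logk_other - fit.logk_phase1
    if gap == 0.0:
        toward: Optional[bool] = None
        signed: Optional[float] = None
    else:
        toward = (shift > 0) == (gap > 0) and shift != 0.0
        signed = shift * math.copysign(1.0, gap)
    return ShiftResult(
        shift=shift,
        relative_shift=relative,
        toward_partner=toward,
        signed_toward_shift=signed,
    )


def fit_sessions(
    sessions: Sequence[SessionRecord], config: FitConfig | None = None
):
    """Batch fit: one row per subject x timepoint, estimates plus shift
    scores and flags. Returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for s in sessions:
        fr = fit_social(s, config)
        sh = compute_shift(fr, s.partner)
        rows.append(
            {
                "subject_id": fr.subject_id,
                "timepoint": fr.timepoint,
                "logk_phase1": fr.logk_phase1,
                "sigma_pref_hat": fr.sigma_pref_hat,
                "logk_phase3": fr.logk_phase3,
                "sigma_phase3_hat": fr.sigma_phase3_hat,
                "sigma_ref_hat": fr.sigma_ref_hat,
                "logk_other": s.partner.logk_other,
                "partner_direction": s.partner.direction,
                "shift": sh.shift,
                "relative_shift": sh.relative_shift,
                "toward_partner": sh.toward_partner,
                "signed_toward_shift": sh.signed_toward_shift,
                "loglik_phase1": fr.loglik_phase1,
                "loglik_phase3": fr.loglik_phase3,
                "loglik_social": fr.loglik_social,
                "boundary_phase1": fr.boundary_phase1,
                "boundary_phase3": fr.boundary_phase3,
                "sigma_ref_flag": fr.sigma_ref_flag,
                "age_baseline": s.params.age_baseline if s.params else np.nan,
                "sigma_pref_true": (
                    s.sigma_pref_session
                    if s.sigma_pref_session is not None
                    else (s.params.sigma_pref_true if s.params else np.nan)
                ),
                "mu_logk_true": s.params.mu_logk_true if s.params else np.nan,
                "sigma_ref_true": s.params.sigma_ref_true if s.params else np.nan,
            }
        )
    return pd.DataFrame(rows)
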