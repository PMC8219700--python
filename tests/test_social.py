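"""Partner assignment, phase-2 learning, the conformity update, and the
session simulator."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from peershift import (
    DiscountBelief,
    OfferPair,
    PartnerSpec,
    ReferenceModel,
    SubjectParams,
    TaskConfig,
    assign_partner,
    indifference_logk,
    run_phase2,
    score_other_choice,
    simulate_session,
    social_update,
)
from peershift.fitting import fit_phase

PAIR = OfferPair(50, 100, 30)


class TestAssignPartner:
    def test_toward_displacement_arithmetic(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            spec = assign_partner(-6.0, -4.0, 1.0, rng)
            if spec.direction == "toward_mean":
                assert spec.logk_other == pytest.approx(-5.0)
            else:
                assert spec.logk_other == pytest.approx(-7.0)

    def test_displacement_is_exactly_one_population_sd(self):
        rng = np.random.default_rng(1)
        for sd in (0.7, 1.5):
            spec = assign_partner(-3.0, -4.6, sd, rng)
            assert abs(spec.logk_other - (-3.0)) == pytest.approx(sd)

    def test_toward_fraction_is_two_thirds(self):
        rng = np.random.default_rng(2)
        n = 10_000
        toward = sum(
            assign_partner(-6.0, -4.0, 1.0, rng).direction == "toward_mean"
            for _ in range(n)
        )
        se = math.sqrt((2 / 3) * (1 / 3) / n)
        assert abs(toward / n - 2 / 3) < 4 * se

    def test_subject_at_population_mean_gets_random_sign(self):
        rng = np.random.default_rng(3)
        others = {assign_partner(-4.0, -4.0, 1.0, rng).logk_other for _ in range(100)}
        assert others == {-5.0, -3.0}

    def test_invalid_inputs(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            assign_partner(-6.0, -4.0, 0.0, rng)
        with pytest.raises(ValueError):
            assign_partner(float("nan"), -4.0, 1.0, rng)


class TestScoreOtherChoice:
    def test_patient_partner_delayed_is_correct(self):
        assert score_other_choice("delayed", PAIR, indifference_logk(PAIR) - 1)

    def test_impatient_partner_delayed_is_wrong(self):
        assert not score_other_choice("delayed", PAIR, indifference_logk(PAIR) + 1)

    def test_exact_indifference_ties_to_delayed(self):
        k_star = indifference_logk(PAIR)
        assert score_other_choice("delayed", PAIR, k_star)
        assert not score_other_choice("immediate", PAIR, k_star)


class _ScriptedLearner:
    """Learner whose correctness sequence is forced, for stopping-rule
    tests: it knows the partner's preference on `correct` trials and
    inverts it otherwise."""

    def __init__(self, logk_other, correct_from=None, always=None):
        self.logk_other = logk_other
        self.correct_from = correct_from
        self.always = always
        self.t = 0
        from peershift import DesignConfig, init_grid

        self.posterior = init_grid(DesignConfig(grid_size=10))

    def propose_pair(self):
        return PAIR

    def choose_for_other(self, pair):
        self.t += 1
        truth = (
            "delayed"
            if self.logk_other <= indifference_logk(pair)
            else "immediate"
        )
        wrong = "immediate" if truth == "delayed" else "delayed"
        if self.always is not None:
            return truth if self.always else wrong
        return truth if self.t >= self.correct_from else wrong

    def observe(self, pair, partner_choice):
        pass


class TestPhase2StoppingRule:
    partner = PartnerSpec(logk_other=-5.0, direction="toward_mean")

    def test_always_correct_stops_at_floor(self, task_config):
        learner = _ScriptedLearner(-5.0, always=True)
        choices, _ = run_phase2(learner, self.partner, task_config)
        assert len(choices) == task_config.phase2_floor == 20

    def test_always_wrong_stops_at_ceiling(self, task_config):
        learner = _ScriptedLearner(-5.0, always=False)
        choices, _ = run_phase2(learner, self.partner, task_config)
        assert len(choices) == task_config.phase2_ceiling == 60
        assert not any(c.feedback_correct for c in choices)

    def test_correct_from_trial_13_stops_at_20(self, task_config):
        """Window trials 11-20 holds exactly 8 correct answers."""
        learner = _ScriptedLearner(-5.0, correct_from=13)
        choices, _ = run_phase2(learner, self.partner, task_config)
        assert len(choices) == 20
        assert sum(c.feedback_correct for c in choices[-10:]) == 8

    def test_correct_from_trial_14_stops_at_21(self, task_config):
        """One trial later, the 8th correct in-window answer arrives at 21."""
        learner = _ScriptedLearner(-5.0, correct_from=14)
        choices, _ = run_phase2(learner, self.partner, task_config)
        assert len(choices) == 21

    def test_floor_binds_even_with_early_streak(self, task_config):
        """8 correct answers before trial 20 never stop the phase early:
        the 20-trial minimum applies independently of the window."""
        learner = _ScriptedLearner(-5.0, correct_from=1)
        choices, _ = run_phase2(learner, self.partner, task_config)
        assert len(choices) == 20


def brute_force_social_posterior_mean(mu_s, var_s, mu_o, var_o, var_ref):
    """Numerical double-grid marginalization over the latent common mean
    m and the partner's log-k (independent oracle for social_update)."""
    m = np.linspace(mu_o - 12, mu_o + 12, 1501)
    k = np.linspace(mu_s - 12, mu_s + 12, 1501)
    # p(m | other data): integrate k_other out of N(k_o; m, var_ref) N(k_o; mu_o, var_o)
    if var_o == 0:
        p_m = norm.pdf(mu_o, m, np.sqrt(var_ref))
    else:
        k_o = np.linspace(mu_o - 12, mu_o + 12, 1501)
        joint = norm.pdf(k_o[None, :], m[:, None], np.sqrt(var_ref)) * norm.pdf(
            k_o[None, :], mu_o, np.sqrt(var_o)
        )
        p_m = np.trapezoid(joint, k_o, axis=1)
    pred = np.trapezoid(
        norm.pdf(k[:, None], m[None, :], np.sqrt(var_ref)) * p_m[None, :], m, axis=1
    )
    post = norm.pdf(k, mu_s, np.sqrt(var_s)) * pred
    post /= np.trapezoid(post, k)
    return float(np.trapezoid(k * post, k))


class TestSocialUpdate:
    def test_closed_form_example(self):
        """sigma_pref^2=1, sigma_ref^2=0.5, exact partner knowledge:
        shift weight 1/2, posterior mean -3."""
        out = social_update(
            DiscountBelief(-4.0, 1.0), -2.0, 0.0, ReferenceModel(math.sqrt(0.5))
        )
        assert out.mu == pytest.approx(-3.0)
        assert out.sigma**2 == pytest.approx(0.5)

    def test_matches_brute_force_marginalization(self):
        """Closed form vs numerical double-grid marginalization over a
        5x5x5 parameter sweep: posterior mean agrees to < 1e-3."""
        for sp in (0.3, 0.7, 1.0, 1.5, 2.0):
            for sr in (0.3, 0.5, 0.8, 1.2, 2.0):
                for vo in (0.0, 0.05, 0.2, 0.5, 1.0):
                    out = social_update(
                        DiscountBelief(-4.0, sp), -2.0, vo, ReferenceModel(sr)
                    )
                    oracle = brute_force_social_posterior_mean(
                        -4.0, sp**2, -2.0, vo, sr**2
                    )
                    assert abs(out.mu - oracle) < 1e-3

    def test_zero_preference_uncertainty_limit(self):
        out = social_update(
            DiscountBelief(-4.0, 1e-6), -2.0, 0.1, ReferenceModel(0.5)
        )
        assert out.mu == pytest.approx(-4.0, abs=1e-6)

    def test_irrelevant_other_limit(self):
        out = social_update(
            DiscountBelief(-4.0, 1.0), -2.0, 0.1, ReferenceModel(1e4)
        )
        assert out.mu == pytest.approx(-4.0, abs=1e-6)

    def test_weight_monotonicity_by_finite_differences(self):
        """Shift weight increases in sigma_pref, decreases in sigma_ref
        and in the partner-posterior variance."""

        def weight(sp, sr, vo):
            out = social_update(
                DiscountBelief(0.0, sp), 1.0, vo, ReferenceModel(sr)
            )
            return out.mu  # equals w since mu_self=0, mu_other=1

        sps = np.linspace(0.2, 3.0, 8)
        srs = np.linspace(0.2, 3.0, 8)
        vos = np.linspace(0.0, 2.0, 8)
        for sr in srs[::3]:
            for vo in vos[::3]:
                ws = [weight(sp, sr, vo) for sp in sps]
                assert all(np.diff(ws) > 0)
                assert all(0 <= w < 1 for w in ws)
        for sp in sps[::3]:
            for vo in vos[::3]:
                ws = [weight(sp, sr, vo) for sr in srs]
                assert all(np.diff(ws) < 0)
        for sp in sps[::3]:
            for sr in srs[::3]:
                ws = [weight(sp, sr, vo) for vo in vos]
                assert all(np.diff(ws) < 0)

    def test_information_never_hurts(self):
        """Posterior variance after the social update never exceeds the
        prior preference variance."""
        rng = np.random.default_rng(0)
        for _ in range(100):
            sp = rng.uniform(0.1, 3)
            out = social_update(
                DiscountBelief(rng.normal(-4, 1), sp),
                rng.normal(-4, 1),
                rng.uniform(0, 2),
                ReferenceModel(rng.uniform(0.1, 3)),
            )
            assert out.sigma <= sp + 1e-12

    def test_invalid_variances_rejected(self):
        with pytest.raises(ValueError):
            social_update(DiscountBelief(-4, 1.0), -2.0, -0.1, ReferenceModel(0.5))
        with pytest.raises(ValueError):
            ReferenceModel(0.0)


class TestSimulateSession:
    def test_phase_trial_counts(self, session, task_config):
        p1 = session.phase_choices(1)
        p3_self = session.phase_choices(3, agent="self")
        p3_other = session.phase_choices(3, agent="other")
        assert len(p1) == task_config.n_phase1 == 60
        assert all(c.agent == "self" for c in p1)
        assert len(p3_self) == 30
        assert len(p3_other) == 30
        assert (
            task_config.phase2_floor
            <= session.phase2_stop_trial
            <= task_config.phase2_ceiling
        )

    def test_phase3_alternates_blocks_of_10_self_first(self, session):
        p3 = session.phase_choices(3)
        agents = [c.agent for c in p3]
        expected = (["self"] * 10 + ["other"] * 10) * 3
        assert agents == expected

    def test_fixed_seed_reproducible(self, subject, task_config):
        s1 = simulate_session(subject, task_config, rng=99)
        s2 = simulate_session(subject, task_config, rng=99)
        assert s1 == s2

    def test_partner_displaced_one_sd_from_phase1_estimate(self, session, task_config):
        assert abs(session.partner.logk_other - session.logk_hat_phase1) == (
            pytest.approx(task_config.population_sd)
        )

    def test_feedback_only_on_other_trials(self, session):
        for c in session.choices:
            assert (c.feedback_correct is not None) == (c.agent == "other")

    def test_certain_subject_does_not_shift(self, task_config):
        """sigma_pref -> 0: phase-3 fitted log-k equals the phase-1 fit
        within estimation error (shift weight ~ 0)."""
        params = SubjectParams(
            subject_id="certain",
            age_baseline=22.0,
            mu_logk_true=-4.0,
            sigma_pref_true=0.02,
            sigma_ref_true=0.7,
            followup_interval=1.5,
        )
        shifts = []
        for seed in range(5):
            s = simulate_session(params, task_config, rng=seed)
            f1 = fit_phase(s.phase_choices(1, agent="self"))
            f3 = fit_phase(s.phase_choices(3, agent="self"))
            shifts.append(f3.mu - f1.mu)
        assert abs(float(np.mean(shifts))) < 0.15

    def test_uncertain_subjects_shift_toward_partner(self, task_config):
        """Mean signed shift is toward the partner and grows with the
        generative preference uncertainty (rank order over levels)."""
        rng = np.random.default_rng(10)
        levels = [0.3, 0.9, 1.8]
        mean_shift = []
        for sp in levels:
            shifts = []
            for i in range(25):
                params = SubjectParams(
                    subject_id=f"u{i}",
                    age_baseline=18.0,
                    mu_logk_true=float(rng.normal(-4.6, 1.5)),
                    sigma_pref_true=sp,
                    sigma_ref_true=0.7,
                    followup_interval=1.5,
                )
                s = simulate_session(
                    params, task_config, rng=np.random.default_rng(rng.integers(2**31))
                )
                f1 = fit_phase(s.phase_choices(1, agent="self"))
                f3 = fit_phase(s.phase_choices(3, agent="self"))
                gap = s.partner.logk_other - f1.mu
                shifts.append((f3.mu - f1.mu) * math.copysign(1.0, gap))
            mean_shift.append(float(np.mean(shifts)))
        assert mean_shift[0] < mean_shift[-1]
        assert all(m > -0.05 for m in mean_shift)
        assert mean_shift[-1] > 0.3
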