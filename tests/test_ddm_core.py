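import math

import numpy as np
import pytest

from pulseddm import (
    DDMParams,
    GridSpec,
    IDEAL_PARAMS,
    TaskConfig,
    Trial,
    choice_probability,
    choice_probability_analytic,
    generate_trial,
    propagate_distribution,
    simulate_accumulator,
    tau_from_lambda,
    trial_loglik,
)
from pulseddm.ddm_core import (
    GridError,
    accumulator_moments,
    dataset_loglik,
    simulate_endpoints,
)
from pulseddm.trial_io import TrialSet


def trial_5L3R():
    """The worked single trial: 5 left puffs, 3 right puffs."""
    return Trial(
        puffs_left=(0.3, 0.8, 1.4, 2.2, 3.0),
        puffs_right=(0.5, 1.8, 3.3),
        cue_duration=3.8,
        delay_duration=0.8,
        correct_side="left",
        choice="left",
    )


class TestSimulateAccumulator:
    def test_noise_free_sum_is_evidence_count(self, rng):
        _, a = simulate_accumulator(trial_5L3R(), IDEAL_PARAMS, rng=rng)
        assert a[0, -1] == pytest.approx(-2.0, abs=1e-12)

    @pytest.mark.parametrize("lam", [-2.0, -0.5, 0.0, 0.5])
    def test_single_pulse_leak_matches_closed_form(self, lam, rng):
        t0 = 1.0
        trial = Trial(
            puffs_left=(), puffs_right=(t0,), cue_duration=3.8,
            delay_duration=0.8, correct_side="right",
        )
        _, a = simulate_accumulator(trial, DDMParams(lam=lam), dt=0.001, rng=rng)
        assert a[0, -1] == pytest.approx(
            math.exp(lam * (trial.total_duration - t0)), abs=1e-6
        )

    def test_pure_diffusion_variance(self, rng):
        trial = Trial((), (), 3.8, 0.0, "left")
        params = DDMParams(sigma_a2=0.7)
        ends = simulate_endpoints(trial, params, n_runs=10000, rng=rng)
        target = 0.7 * 3.8
        # chi-squared sampling error of a variance estimate: sd ~ var*sqrt(2/n)
        se = target * math.sqrt(2 / 10000)
        assert abs(ends.var() - target) < 3 * se

    def test_decay_time_constant_closed_form(self, rng):
        # after one time constant, a single pulse decays to 1/e
        lam = -0.5
        tau = tau_from_lambda(lam).tau
        trial = Trial((), (0.5,), 3.8, 0.8, "right")
        times, a = simulate_accumulator(trial, DDMParams(lam=lam), dt=0.001, rng=rng)
        idx = np.argmin(np.abs(times - (0.5 + tau)))
        assert a[0, idx] == pytest.approx(math.exp(-1.0), abs=1e-3)


class TestMomentsAndGrid:
    def test_degenerate_grid_mass_at_evidence_count(self):
        dist = propagate_distribution(trial_5L3R(), IDEAL_PARAMS)
        peak = dist.grid[np.argmax(dist.mass)]
        assert abs(peak - (-2.0)) <= dist.spacing

    def test_mass_conserved(self):
        params = DDMParams(lam=-0.4, sigma_a2=0.6, sigma_s2=1.2, bias=0.3)
        dist = propagate_distribution(trial_5L3R(), params)
        assert dist.mass.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(dist.mass >= -1e-12)

    def test_too_narrow_grid_raises_rather_than_truncating(self):
        params = DDMParams(sigma_a2=1.0, sigma_s2=1.0)
        with pytest.raises(GridError, match="narrow"):
            propagate_distribution(
                trial_5L3R(), params, grid=GridSpec(half_width=1.0)
            )

    def test_grid_matches_analytic_gaussian(self, rng):
        cfg = TaskConfig()
        for _ in range(5):
            t = generate_trial(cfg, "light-off", rng)
            params = DDMParams(
                lam=rng.uniform(-1.5, 0.5), sigma_a2=rng.uniform(0.05, 1.5),
                sigma_s2=rng.uniform(0.05, 1.5), bias=rng.uniform(-1, 1),
                lapse=rng.uniform(0, 0.3),
            )
            p_grid = choice_probability(propagate_distribution(t, params), params)
            p_ana = choice_probability_analytic(t, params)
            assert p_grid == pytest.approx(p_ana, abs=2e-3)

    def test_grid_refinement_changes_little(self, rng):
        t = generate_trial(TaskConfig(), "light-off", rng)
        params = DDMParams(lam=-0.6, sigma_a2=0.5, sigma_s2=1.0, bias=0.2,
                           lapse=0.1)
        coarse = choice_probability(
            propagate_distribution(t, params, grid=GridSpec(spacing=0.02), dt=0.015),
            params,
        )
        fine = choice_probability(
            propagate_distribution(t, params, grid=GridSpec(spacing=0.01), dt=0.0075),
            params,
        )
        assert abs(fine - coarse) < 1e-3

    def test_moments_against_simulation(self, rng):
        t = trial_5L3R()
        params = DDMParams(lam=-0.8, sigma_a2=0.9, sigma_s2=0.5)
        mu, var = accumulator_moments(t, params)
        ends = simulate_endpoints(t, params, n_runs=20000, rng=rng)
        assert ends.mean() == pytest.approx(mu, abs=4 * math.sqrt(var / 20000))
        assert ends.var() == pytest.approx(var, rel=0.1)


class TestChoiceProbability:
    def test_lapse_caps_probability(self):
        t = Trial((), (0.5, 1.0, 1.5), 3.8, 0.8, "right")  # all mass right
        params = DDMParams(lapse=0.2)
        dist = propagate_distribution(t, params)
        assert choice_probability(dist, params) == pytest.approx(0.9, abs=1e-9)

    def test_full_lapse_is_chance(self):
        t = trial_5L3R()
        params = DDMParams(sigma_s2=0.5, lapse=1.0)
        dist = propagate_distribution(t, params)
        assert choice_probability(dist, params) == pytest.approx(0.5, abs=1e-12)

    def test_symmetric_distribution_gives_half(self):
        t = Trial((0.5,), (1.5,), 3.8, 0.8, "right")
        params = DDMParams(sigma_s2=0.8)
        dist = propagate_distribution(t, params)
        assert choice_probability(dist, params) == pytest.approx(0.5, abs=1e-6)

    def test_mirror_antisymmetry_exact(self, rng):
        cfg = TaskConfig()
        params = DDMParams(lam=-0.5, sigma_a2=0.3, sigma_s2=0.9, bias=0.4,
                           lapse=0.15)
        mirrored = params.replace(bias=-params.bias)
        for _ in range(5):
            t = generate_trial(cfg, "light-off", rng)
            t_m = Trial(
                puffs_left=t.puffs_right, puffs_right=t.puffs_left,
                cue_duration=t.cue_duration, delay_duration=t.delay_duration,
                correct_side="left" if t.correct_side == "right" else "right",
            )
            p = choice_probability(propagate_distribution(t, params), params)
            q = choice_probability(propagate_distribution(t_m, mirrored), mirrored)
            assert p + q == pytest.approx(1.0, abs=1e-12)

    def test_lapse_bounds_hold(self, rng):
        cfg = TaskConfig()
        for _ in range(10):
            t = generate_trial(cfg, "light-off", rng)
            lapse = float(rng.uniform(0, 1))
            params = DDMParams(
                lam=rng.uniform(-2, 1), sigma_a2=rng.uniform(0, 3),
                sigma_s2=rng.uniform(0, 3), bias=rng.uniform(-2, 2), lapse=lapse,
            )
            p = choice_probability_analytic(t, params)
            assert lapse / 2 - 1e-12 <= p <= 1 - lapse / 2 + 1e-12

    def test_noise_free_monotone_in_evidence(self):
        ps = []
        for delta in (-3, -1, 1, 3):
            n_r = max(0, delta) + 2
            n_l = n_r - delta
            t = Trial(
                puffs_left=tuple(0.1 + 0.3 * i for i in range(n_l)),
                puffs_right=tuple(0.25 + 0.3 * i for i in range(n_r)),
                cue_duration=3.8, delay_duration=0.8,
                correct_side="right" if delta > 0 else "left",
            )
            ps.append(choice_probability_analytic(t, IDEAL_PARAMS))
        assert all(a <= b for a, b in zip(ps, ps[1:]))


class TestLoglik:
    def test_full_lapse_is_log_half(self):
        t = trial_5L3R()
        params = DDMParams(lapse=1.0)
        for choice in ("left", "right"):
            assert trial_loglik(t, choice, params) == pytest.approx(math.log(0.5))

    def test_ideal_correct_choice_is_log_one(self):
        assert trial_loglik(trial_5L3R(), "left", IDEAL_PARAMS) == 0.0

    def test_grid_and_analytic_engines_agree(self):
        t = trial_5L3R()
        params = DDMParams(lam=-0.3, sigma_a2=0.4, sigma_s2=1.1, bias=0.1,
                           lapse=0.05)
        g = trial_loglik(t, "left", params, engine="grid")
        a = trial_loglik(t, "left", params, engine="analytic")
        assert g == pytest.approx(a, abs=5e-3)

    def test_dataset_additivity_and_order_invariance(self):
        t = trial_5L3R()
        params = DDMParams(sigma_s2=0.5, lapse=0.1)
        single = trial_loglik(t, "left", params)
        ts = TrialSet([t] * 7)
        total, _ = dataset_loglik(ts, params)
        assert total == pytest.approx(7 * single)

    def test_excluded_trials_counted(self):
        t = trial_5L3R()
        short = Trial((0.3,), (0.6, 1.0), 1.5, 0.8, "right", choice="right")
        none_choice = Trial(
            t.puffs_left, t.puffs_right, 3.8, 0.8, "left", choice="none"
        )
        total, n_exc = dataset_loglik(
            TrialSet([t, short, none_choice]), DDMParams(lapse=1.0)
        )
        assert n_exc == 2
        assert total == pytest.approx(math.log(0.5))


class TestTau:
    def test_leaky_label(self):
        tc = tau_from_lambda(-0.5)
        assert tc.tau == pytest.approx(2.0) and tc.label == "leaky"

    def test_zero_lambda_unbounded(self):
        tc = tau_from_lambda(0.0)
        assert math.isinf(tc.tau) and tc.label == "non-leaky"

    def test_unstable_label(self):
        assert tau_from_lambda(1.39).label == "unstable"
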