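import numpy as np
import pytest

from pulseddm import (
    PsychometricFit,
    TaskConfig,
    TrialSet,
    align_weights_to_light,
    apply_impairment,
    bootstrap_weights,
    cv_regression_accuracy,
    fit_choice_regression,
    generate_session,
    shuffle_control,
)
from pulseddm.choice_regression import SeparationError, evidence_matrix
from pulseddm.synthetic_task import ImpairmentScenario
from pulseddm.trial_io import bin_evidence


CURVE = PsychometricFit(y0=0.05, A=0.9, x0=0.0, b=2.0)


def curve_session(n, seed, **cfg_kw):
    gen = np.random.default_rng(seed)
    cfg = TaskConfig(p_long=1.0, light_fraction=0.0, **cfg_kw)
    ts = generate_session(cfg, n_trials=n, rng=gen)
    return apply_impairment(ts, ImpairmentScenario(kind="none"), CURVE, gen)


class TestFitChoiceRegression:
    def test_uniform_agent_has_uniform_positive_weights(self):
        res = fit_choice_regression(curve_session(6000, 11))
        assert np.all(res.weights > 0)
        # pairwise differences inside the joint 99% envelope
        for i in range(3):
            for j in range(i + 1, 3):
                gap = abs(res.weights[i] - res.weights[j])
                assert gap < (res.ci_high[i] - res.ci_low[i])

    def test_first_bin_only_agent(self, rng):
        cfg = TaskConfig(p_long=1.0, light_fraction=0.0)
        ts = generate_session(cfg, n_trials=6000, rng=rng)
        chosen = []
        for t in ts:
            e1 = bin_evidence(t, 3).counts[0]
            p = float(CURVE.prob_right(e1))
            chosen.append(t.with_choice("right" if rng.random() < p else "left"))
        res = fit_choice_regression(TrialSet(chosen))
        assert res.weights[0] > res.ci_high[1] and res.weights[0] > res.ci_high[2]
        assert res.ci_low[1] <= 0 <= res.ci_high[1]
        assert res.ci_low[2] <= 0 <= res.ci_high[2]

    def test_coin_flip_agent_weights_cover_zero(self, rng):
        cfg = TaskConfig(p_long=1.0, light_fraction=0.0)
        ts = generate_session(cfg, n_trials=3000, rng=rng)
        chosen = TrialSet([
            t.with_choice("right" if rng.random() < 0.5 else "left") for t in ts
        ])
        res = fit_choice_regression(chosen)
        assert np.all(res.ci_low <= 0) and np.all(res.ci_high >= 0)

    def test_separation_raises_unless_ridge(self, rng):
        cfg = TaskConfig(p_long=1.0, light_fraction=0.0)
        ts = generate_session(cfg, n_trials=400, rng=rng)
        ideal = TrialSet([t.with_choice(t.correct_side) for t in ts])
        with pytest.raises(SeparationError):
            fit_choice_regression(ideal)
        res = fit_choice_regression(ideal, ridge=True)
        assert np.all(res.weights > 0)
        assert np.all(np.isnan(res.se))

    def test_doubling_evidence_halves_weights(self, rng):
        base = curve_session(8000, 12)
        doubled = []
        for t in base:
            doubled.append(
                type(t)(
                    puffs_left=t.puffs_left + tuple(x + 0.07 for x in t.puffs_left),
                    puffs_right=t.puffs_right + tuple(x + 0.07 for x in t.puffs_right),
                    cue_duration=t.cue_duration,
                    delay_duration=t.delay_duration,
                    correct_side=t.correct_side,
                    choice=t.choice,
                )
            )
        w1 = fit_choice_regression(base).weights
        w2 = fit_choice_regression(TrialSet(doubled)).weights
        np.testing.assert_allclose(w2, w1 / 2, rtol=0.25)


class TestBootstrap:
    def test_sd_close_to_asymptotic_se(self):
        ts = curve_session(5000, 13)
        res = fit_choice_regression(ts)
        sd = bootstrap_weights(ts, n_boot=100, rng=np.random.default_rng(4))
        assert np.all(sd < 2 * res.se) and np.all(sd > res.se / 2)

    def test_duplicated_data_shrinks_sd_by_sqrt2(self):
        ts = curve_session(2500, 14)
        both = TrialSet(list(ts) + list(ts))
        sd1 = bootstrap_weights(ts, n_boot=150, rng=np.random.default_rng(5))
        sd2 = bootstrap_weights(both, n_boot=150, rng=np.random.default_rng(5))
        np.testing.assert_allclose(sd2, sd1 / np.sqrt(2), rtol=0.35)


class TestCvAccuracy:
    def test_strong_evidence_agent_predictable(self):
        gen = np.random.default_rng(15)
        cfg = TaskConfig(p_long=1.0, light_fraction=0.0)
        ts = generate_session(cfg, n_trials=5000, rng=gen)
        # near-deterministic but unseparated: tiny lapse-like flips
        chosen = []
        for t in ts:
            c = t.correct_side if gen.random() > 0.02 else (
                "left" if t.correct_side == "right" else "right"
            )
            chosen.append(t.with_choice(c))
        acc = cv_regression_accuracy(TrialSet(chosen), k=3,
                                     rng=np.random.default_rng(6))
        assert acc > 0.95

    def test_coin_flip_agent_at_chance(self, rng):
        cfg = TaskConfig(p_long=1.0, light_fraction=0.0)
        ts = generate_session(cfg, n_trials=4000, rng=rng)
        chosen = TrialSet([
            t.with_choice("right" if rng.random() < 0.5 else "left") for t in ts
        ])
        acc = cv_regression_accuracy(chosen, rng=np.random.default_rng(7))
        assert abs(acc - 0.5) < 3 * np.sqrt(0.25 / 4000)

    def test_reproducible_under_fixed_seed(self):
        ts = curve_session(1000, 16)
        a = cv_regression_accuracy(ts, rng=np.random.default_rng(8))
        b = cv_regression_accuracy(ts, rng=np.random.default_rng(8))
        assert a == b


class TestAlignment:
    def test_two_condition_hand_example(self):
        res = {
            "first-third": np.array([0.3, 0.2, 0.1]),
            "middle-third": np.array([0.25, 0.35, 0.15]),
        }
        aligned = align_weights_to_light(res)
        lag = dict(zip(aligned.lags.tolist(), aligned.mean.tolist()))
        # lag +1: bin after light = first-third bin 2 and middle-third bin 3
        assert lag[1] == pytest.approx((0.2 + 0.15) / 2)
        assert lag[0] == pytest.approx((0.3 + 0.35) / 2)
        assert lag[-1] == pytest.approx(0.25)  # only middle-third has a bin before
        assert lag[2] == pytest.approx(0.1)

    def test_single_condition_is_reindexing(self):
        w = np.array([0.4, 0.3, 0.2])
        aligned = align_weights_to_light({"last-third": w})
        lag = dict(zip(aligned.lags.tolist(), aligned.mean.tolist()))
        assert lag[0] == pytest.approx(0.2)
        assert lag[-1] == pytest.approx(0.3)
        assert lag[-2] == pytest.approx(0.4)
        assert np.isnan(lag[1]) and np.isnan(lag[2])

    def test_identical_conditions_average_to_themselves(self):
        w = np.array([0.3, 0.3, 0.3])
        aligned = align_weights_to_light(
            {c: w for c in ("first-third", "middle-third", "last-third")}
        )
        valid = ~np.isnan(aligned.mean)
        np.testing.assert_allclose(aligned.mean[valid], 0.3)


@pytest.fixture(scope="module")
def impaired_session():
    gen = np.random.default_rng(18)
    cfg = TaskConfig(
        p_long=1.0, light_fraction=0.6,
        light_schedule={"first-third": 1 / 3, "middle-third": 1 / 3,
                        "last-third": 1 / 3},
    )
    ts = generate_session(cfg, n_trials=9000, rng=gen)
    return apply_impairment(
        ts, ImpairmentScenario(kind="retention"), CURVE, gen
    )


class TestShuffleControl:
    def test_shuffle_flattens_retention_alignment(self, impaired_session):
        gen = np.random.default_rng(9)
        shuf = shuffle_control(impaired_session, rng=gen, n_boot=60)
        valid = ~np.isnan(shuf.mean)
        grand = np.nanmean(shuf.mean)
        assert np.all(
            np.abs(shuf.mean[valid] - grand) <= 3 * shuf.boot_sd[valid]
        )

    def test_unshuffled_alignment_shows_pre_light_depression(self, impaired_session):
        from pulseddm.choice_regression import _per_condition_results

        results, boots = _per_condition_results(
            impaired_session,
            ["first-third", "middle-third", "last-third"],
            np.random.default_rng(10), 60, 3,
        )
        aligned = align_weights_to_light(results, boots)
        lag = dict(zip(aligned.lags.tolist(), aligned.mean.tolist()))
        sd = dict(zip(aligned.lags.tolist(), aligned.boot_sd.tolist()))
        # pre-light weights depressed well below the light-bin weight
        assert lag[-1] < lag[0] - 3 * np.hypot(sd[-1], sd[0])

    def test_reproducible_under_fixed_seed(self, impaired_session):
        a = shuffle_control(impaired_session, rng=np.random.default_rng(11))
        b = shuffle_control(impaired_session, rng=np.random.default_rng(11))
        valid = ~np.isnan(a.mean)
        np.testing.assert_array_equal(a.mean[valid], b.mean[valid])


class TestEvidenceMatrix:
    def test_filters_and_shapes(self, small_session, rng):
        chosen = TrialSet([
            t.with_choice("right" if rng.random() < 0.5 else "left")
            for t in small_session
        ])
        X, y = evidence_matrix(chosen)
        n_expected = sum(
            1 for t in chosen
            if not t.guided and abs(t.cue_duration - 3.8) < 1e-6
        )
        assert X.shape == (n_expected, 3) and len(y) == n_expected
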