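"""Synthetic task generator and behavioral agents.

Emulates the somatosensory evidence-accumulation task: independent left and
right trains of randomly timed air puffs at a mean rate of 2.5 Hz per side
with a 200-ms minimum inter-puff interval, over a 3.8-s (p = 0.85) or 1.5-s
(p = 0.15) cue period, followed by an 800-ms delay. Optogenetic-style light
windows are interleaved on a random 15-30% of trials (full cue period, one
third of the cue period, or the delay). Choices are produced either by a
drift-diffusion agent (:func:`ddm_agent`, :func:`simulate_choices_ddm`) or
by sampling from a psychometric curve, optionally with one of the impairment
interventions (sensation, retention, action, lapse-flip) applied.

Puff trains are renewal processes with inter-event intervals
``min_gap + Exponential(mean 1/rate - min_gap)``, so both the mean rate and
the refractory gap are exact in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Protocol

import numpy as np

from .ddm_core import DDMParams, simulate_endpoints
from .trial_io import CONDITION_LABELS, LightWindow, Trial, TrialSet

__all__ = [
    "TaskConfig",
    "ImpairmentScenario",
    "ChoiceCurve",
    "StepCurve",
    "generate_puff_train",
    "generate_trial",
    "generate_session",
    "psychometric_agent",
    "ddm_agent",
    "simulate_choices_ddm",
    "apply_impairment",
]

#: Default mix of light-on conditions within a session (uniform over the
#: five cue/delay delivery windows used in the study).
DEFAULT_LIGHT_SCHEDULE = {
    "full-cue": 0.2,
    "first-third": 0.2,
    "middle-third": 0.2,
    "last-third": 0.2,
    "delay": 0.2,
}


@dataclass(frozen=True)
class TaskConfig:
    """Stimulus and session statistics of the task.

    Defaults are the task's stated parameters: 2.5 puffs/s per side with a
    200-ms refractory gap, 3.8-s cue with probability 0.85 (else 1.5 s),
    800-ms delay, light on 15-30% of trials, 200-300 trials per session.
    ``lick_latency`` is the mean latency from end of delay to the decision
    lick (0.578 s, with Gaussian jitter of s.d. ``lick_latency_sd``).
    """

    puff_rate: float = 2.5
    min_gap: float = 0.2
    long_cue: float = 3.8
    short_cue: float = 1.5
    p_long: float = 0.85
    delay: float = 0.8
    light_fraction: float = 0.2
    light_schedule: dict = field(
        default_factory=lambda: dict(DEFAULT_LIGHT_SCHEDULE)
    )
    session_size: tuple[int, int] = (200, 300)
    lick_latency: float = 0.578
    lick_latency_sd: float = 0.222

    def __post_init__(self):
        if 1.0 / self.puff_rate < self.min_gap:
            raise ValueError(
                f"mean inter-puff interval 1/{self.puff_rate} Hz is shorter "
                f"than the minimum gap {self.min_gap} s"
            )
        for name in ("p_long", "light_fraction"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        unknown = set(self.light_schedule) - CONDITION_LABELS
        if unknown:
            raise ValueError(f"unknown light conditions: {sorted(unknown)}")


@dataclass(frozen=True)
class ImpairmentScenario:
    """A simulated perturbation applied when generating choices.

    kind         : none | sensation | retention | action | lapse_flip
    attenuation  : weight given to affected puffs (sensation: puffs during
                   the light window; retention: puffs before light onset)
    flip_fraction: fraction of trials whose choice is inverted (lapse_flip)
    action_scale : kappa (s); in the action scenario a drawn choice is
                   flipped with probability min(1, kappa / time from light
                   offset to the decision lick)
    """

    kind: str = "none"
    attenuation: float = 0.5
    flip_fraction: float = 0.25
    action_scale: float = 0.4

    def __post_init__(self):
        if self.kind not in ("none", "sensation", "retention", "action", "lapse_flip"):
            raise ValueError(f"unknown impairment kind {self.kind!r}")
        if not 0.0 <= self.attenuation <= 1.0:
            raise ValueError(f"attenuation must be in [0, 1], got {self.attenuation}")
        if not 0.0 <= self.flip_fraction <= 1.0:
            raise ValueError(
                f"flip_fraction must be in [0, 1], got {self.flip_fraction}"
            )
        if self.action_scale <= 0:
            raise ValueError(f"action_scale must be > 0, got {self.action_scale}")


class ChoiceCurve(Protocol):
    """Anything mapping signed evidence #R - #L to P(rightward choice)."""

    def prob_right(self, delta) -> np.ndarray: ...


@dataclass(frozen=True)
class StepCurve:
    """Ideal-observer curve: P(right) = 1 for delta > 0, 0 below, 0.5 at 0."""

    def prob_right(self, delta):
        return 0.5 * (np.sign(np.asarray(delta, dtype=float)) + 1.0)


def generate_puff_train(
    rate: float,
    min_gap: float,
    duration: float,
    rng: np.random.Generator,
) -> tuple[float, ...]:
    """One renewal-process puff train over ``[0, duration)``.

    Inter-event intervals (including the wait to the first event from time
    0) are ``min_gap + Exponential(mean 1/rate - min_gap)``, giving a mean
    event rate of exactly ``rate`` with no two events closer than
    ``min_gap``.
    """
    if duration < 0:
        raise ValueError(f"duration must be >= 0, got {duration}")
    mean_exp = 1.0 / rate - min_gap
    if mean_exp < 0:
        raise ValueError(
            f"1/rate = {1.0 / rate:.3f} s must be >= min_gap = {min_gap} s"
        )
    times = []
    t = 0.0
    while True:
        t += min_gap + rng.exponential(mean_exp)
        if t >= duration:
            break
        times.append(t)
    return tuple(times)


_THIRD_CONDITIONS = {"first-third": 0, "middle-third": 1, "last-third": 2}


def _light_window_for(condition: str, cue: float, delay: float) -> Optional[LightWindow]:
    if condition in ("light-off", "guided"):
        return None
    if condition == "full-cue":
        return LightWindow(0.0, cue, "bilateral")
    if condition in _THIRD_CONDITIONS:
        i = _THIRD_CONDITIONS[condition]
        return LightWindow(i * cue / 3.0, (i + 1) * cue / 3.0, "bilateral")
    if condition == "delay":
        return LightWindow(cue, cue + delay, "bilateral")
    if condition == "delay-200ms":
        return LightWindow(cue, cue + min(0.2, delay), "bilateral")
    if condition == "delay-500ms":
        return LightWindow(cue, cue + min(0.5, delay), "bilateral")
    raise ValueError(f"unknown condition {condition!r}")


def generate_trial(
    config: TaskConfig,
    condition: str,
    rng: np.random.Generator,
    max_retries: int = 1000,
) -> Trial:
    """One stimulus trial (choice unset) under the given light condition.

    Tie trials (#R = #L over the cue period) are regenerated, because the
    correct side is undefined for ties. Guided trials carry a single-sided
    cue train plus regular 2.5-Hz guide puffs during the delay.
    """
    if condition not in CONDITION_LABELS:
        raise ValueError(f"unknown condition {condition!r}")
    cue = config.long_cue if rng.random() < config.p_long else config.short_cue
    lw = _light_window_for(condition, cue, config.delay)

    if condition == "guided":
        side = "right" if rng.random() < 0.5 else "left"
        for _ in range(max_retries):
            train = generate_puff_train(config.puff_rate, config.min_gap, cue, rng)
            if train:
                break
        else:
            raise RuntimeError("could not generate a non-empty guided cue train")
        # regular guide puffs through the delay, spaced at the mean interval
        step = 1.0 / config.puff_rate
        guide = tuple(
            cue + config.min_gap + k * step
            for k in range(int(math.ceil(config.delay / step)))
            if cue + config.min_gap + k * step < cue + config.delay
        )
        puffs = train + guide
        return Trial(
            puffs_left=puffs if side == "left" else (),
            puffs_right=puffs if side == "right" else (),
            cue_duration=cue,
            delay_duration=config.delay,
            correct_side=side,
            light_window=lw,
            guided=True,
            condition_label=condition,
        )

    for _ in range(max_retries):
        left = generate_puff_train(config.puff_rate, config.min_gap, cue, rng)
        right = generate_puff_train(config.puff_rate, config.min_gap, cue, rng)
        if len(left) != len(right):
            break
    else:
        raise RuntimeError("could not generate a non-tie trial")
    return Trial(
        puffs_left=left,
        puffs_right=right,
        cue_duration=cue,
        delay_duration=config.delay,
        correct_side="right" if len(right) > len(left) else "left",
        light_window=lw,
        guided=False,
        condition_label=condition,
    )


def _draw_latency(config: TaskConfig, rng: np.random.Generator) -> float:
    lat = config.lick_latency + config.lick_latency_sd * rng.standard_normal()
    return max(lat, 0.05)


def generate_session(
    config: TaskConfig,
    n_trials: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    subject_id: str = "sim",
    session_id: str = "0",
) -> TrialSet:
    """A session of trials with light-on conditions interleaved at random.

    Each trial is light-on with probability ``config.light_fraction``; the
    light condition is drawn from ``config.light_schedule``. Decision
    latencies are synthesized for every trial; choices are left unset.
    """
    rng = np.random.default_rng() if rng is None else rng
    if n_trials is None:
        lo, hi = config.session_size
        n_trials = int(rng.integers(lo, hi + 1))
    if n_trials < 1:
        raise ValueError(f"n_trials must be >= 1, got {n_trials}")
    labels = list(config.light_schedule)
    weights = np.array([config.light_schedule[c] for c in labels], dtype=float)
    if labels and weights.sum() > 0:
        weights = weights / weights.sum()
    trials = []
    for _ in range(n_trials):
        if labels and rng.random() < config.light_fraction:
            cond = labels[rng.choice(len(labels), p=weights)]
        else:
            cond = "light-off"
        t = generate_trial(config, cond, rng)
        t.decision_latency = _draw_latency(config, rng)
        trials.append(t)
    ts = TrialSet(trials, subject_id=subject_id, session_id=session_id)
    ts.validate()
    return ts


# ---------------------------------------------------------------------------
# behavioral agents

def psychometric_agent(
    trial: Trial, curve: ChoiceCurve, rng: np.random.Generator
) -> str:
    """Bernoulli choice at the curve's P(right) for the trial's #R - #L."""
    p = float(np.clip(curve.prob_right(trial.delta), 0.0, 1.0))
    return "right" if rng.random() < p else "left"


def ddm_agent(
    trial: Trial,
    params: DDMParams,
    dt: float = 0.015,
    rng: Optional[np.random.Generator] = None,
) -> str:
    """Choice from one forward simulation of the accumulator.

    The trajectory is simulated to the end of the trial; the choice is
    rightward when the final accumulator value exceeds the bias threshold
    (ties split at random), and on a ``lapse`` fraction of trials the choice
    is replaced by a coin flip.
    """
    rng = np.random.default_rng() if rng is None else rng
    a_end = float(simulate_endpoints(trial, params, n_runs=1, dt=dt, rng=rng)[0])
    if params.lapse > 0 and rng.random() < params.lapse:
        return "right" if rng.random() < 0.5 else "left"
    if a_end == params.bias:
        return "right" if rng.random() < 0.5 else "left"
    return "right" if a_end > params.bias else "left"


def simulate_choices_ddm(
    trials: TrialSet,
    params: DDMParams,
    dt: float = 0.015,
    rng: Optional[np.random.Generator] = None,
) -> TrialSet:
    """Assign drift-diffusion choices to every trial, vectorized over trials.

    Forward-simulates the accumulator for all trials simultaneously on a
    shared ``dt`` time grid (puffs applied in the step containing their
    onset), which matches per-trial simulation up to O(dt) puff-timing
    quantization. Returns a new TrialSet; the input is not modified.
    """
    rng = np.random.default_rng() if rng is None else rng
    n = len(trials)
    durations = np.array([t.total_duration for t in trials])
    n_steps = int(math.ceil(durations.max() / dt))
    # per-puff flat arrays: owning trial, time step, sign
    p_trial, p_step, p_sign = [], [], []
    for i, t in enumerate(trials):
        for sign, times in ((1.0, t.puffs_right), (-1.0, t.puffs_left)):
            for tt in times:
                p_trial.append(i)
                p_step.append(min(int(tt / dt), n_steps - 1))
                p_sign.append(sign)
    p_trial = np.asarray(p_trial, dtype=int)
    p_step = np.asarray(p_step, dtype=int)
    p_sign = np.asarray(p_sign, dtype=float)
    order = np.argsort(p_step, kind="stable")
    p_trial, p_step, p_sign = p_trial[order], p_step[order], p_sign[order]
    starts = np.searchsorted(p_step, np.arange(n_steps + 1))

    decay = math.exp(params.lam * dt)
    v_step = (
        params.sigma_a2 * dt
        if abs(params.lam) < 1e-12
        else params.sigma_a2 * (math.exp(2 * params.lam * dt) - 1) / (2 * params.lam)
    )
    sd_step = math.sqrt(v_step)
    sd_s = math.sqrt(params.sigma_s2)

    a = np.zeros(n)
    active_after = np.ceil(durations / dt).astype(int)  # steps each trial runs
    for s in range(n_steps):
        live = active_after > s
        a[live] = a[live] * decay
        if sd_step > 0:
            a[live] += sd_step * rng.standard_normal(int(live.sum()))
        lo, hi = starts[s], starts[s + 1]
        if hi > lo:
            amp = p_sign[lo:hi]
            if sd_s > 0:
                amp = amp * (1.0 + sd_s * rng.standard_normal(hi - lo))
            np.add.at(a, p_trial[lo:hi], amp)

    go_right = a > params.bias
    ties = a == params.bias
    if ties.any():
        go_right = go_right | (ties & (rng.random(n) < 0.5))
    if params.lapse > 0:
        lapsed = rng.random(n) < params.lapse
        go_right = np.where(lapsed, rng.random(n) < 0.5, go_right)

    out = [
        replace(t, choice="right" if r else "left")
        for t, r in zip(trials, go_right)
    ]
    return TrialSet(out, trials.subject_id, trials.session_id, trials.condition_label)


# ---------------------------------------------------------------------------
# impairment interventions

def _effective_delta(trial: Trial, scenario: ImpairmentScenario) -> float:
    """Signed evidence with affected puffs down-weighted.

    sensation: puffs whose onset falls inside the light window carry weight
    ``attenuation``; retention: puffs with onset strictly before light onset
    do. All other puffs carry weight 1.
    """
    lw = trial.light_window
    total = 0.0
    for sign, times in ((1.0, trial.puffs_right), (-1.0, trial.puffs_left)):
        for t in times:
            if t >= trial.cue_duration:
                continue
            if scenario.kind == "sensation":
                affected = lw.start <= t < lw.end
            else:  # retention
                affected = t < lw.start
            total += sign * (scenario.attenuation if affected else 1.0)
    return total


def apply_impairment(
    trials: TrialSet,
    scenario: ImpairmentScenario,
    curve: ChoiceCurve,
    rng: np.random.Generator,
) -> TrialSet:
    """Simulate choices from the psychometric curve under an intervention.

    Light-off trials always receive plain curve draws. On light-on trials:
    ``sensation`` and ``retention`` down-weight the affected puffs and draw
    the choice from the curve at the effective (possibly non-integer)
    evidence value; ``action`` draws normally, then flips the choice with
    probability ``min(1, kappa / time from light offset to the decision
    lick)``; ``lapse_flip`` flips a uniformly random ``flip_fraction`` of
    all trials (light-on or not). Returns a new TrialSet.
    """
    needs_light = scenario.kind in ("sensation", "retention", "action")
    if needs_light and not any(t.light_window is not None for t in trials):
        raise ValueError(
            f"scenario {scenario.kind!r} requires light windows but no trial "
            "has one"
        )
    out = []
    for t in trials:
        lw = t.light_window
        if scenario.kind in ("sensation", "retention") and lw is not None:
            x = _effective_delta(t, scenario)
        else:
            x = float(t.delta)
        p = float(np.clip(curve.prob_right(x), 0.0, 1.0))
        choice = "right" if rng.random() < p else "left"
        if scenario.kind == "action" and lw is not None:
            latency = t.decision_latency if t.decision_latency is not None else 0.578
            lick_time = t.cue_duration + t.delay_duration + latency
            gap = max(lick_time - lw.end, 1e-9)
            if rng.random() < min(1.0, scenario.action_scale / gap):
                choice = "left" if choice == "right" else "right"
        out.append(replace(t, choice=choice))
    if scenario.kind == "lapse_flip" and len(out):
        n_flip = int(round(scenario.flip_fraction * len(out)))
        for i in rng.choice(len(out), size=n_flip, replace=False):
            out[i].choice = "left" if out[i].choice == "right" else "right"
    return TrialSet(out, trials.subject_id, trials.session_id, trials.condition_label)
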