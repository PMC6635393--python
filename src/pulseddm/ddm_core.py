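"""The five-parameter pulse accumulator model.

A scalar accumulator ``a`` starts at 0 at cue onset and evolves as

    da = sigma_a dW + lambda * a dt + (right puffs: +eta, left puffs: -eta)

with per-puff amplitudes ``eta ~ N(1, sigma_s)`` i.i.d., continuous diffusion
noise of variance ``sigma_a2`` per unit time, and exponential drift ``lambda``
(negative = leaky memory, positive = unstable). At the end of the trial (cue
period plus delay) the choice is rightward when ``a`` exceeds the bias
threshold, except on a ``lapse`` fraction of trials where the choice is a
coin flip.

Because the model has no absorbing bound, the accumulator given the puff
times is exactly Gaussian:

    mean(T)     = sum_i s_i * exp(lambda * (T - t_i))
    variance(T) = sigma_s2 * sum_i exp(2*lambda*(T - t_i))
                  + sigma_a2 * (exp(2*lambda*T) - 1) / (2*lambda)

with ``s_i = +1`` for right puffs and ``-1`` for left puffs (and the
``sigma_a2`` term reducing to ``sigma_a2 * T`` as ``lambda -> 0``). Three
independent routes to the rightward-choice probability are provided and
cross-checked in the test suite: this closed form (:func:`choice_probability_analytic`),
a discretized Fokker-Planck-style grid propagation of the accumulator
distribution (:func:`propagate_distribution`), and forward Monte-Carlo
simulation (:func:`simulate_accumulator` / :func:`simulate_endpoints`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
from scipy.stats import norm

from .trial_io import Trial

__all__ = [
    "DDMParams",
    "IDEAL_PARAMS",
    "AccumulatorDistribution",
    "GridSpec",
    "GridError",
    "TimeConstant",
    "accumulator_moments",
    "simulate_accumulator",
    "simulate_endpoints",
    "propagate_distribution",
    "choice_probability",
    "choice_probability_analytic",
    "trial_loglik",
    "dataset_loglik",
    "tau_from_lambda",
]

# probability mass tolerance for conservation / boundary checks
_MASS_TOL = 1e-9
_BOUNDARY_TOL = 1e-8


@dataclass(frozen=True)
class DDMParams:
    """Parameters of the pulse accumulator.

    lam      : drift coefficient (1/s); lam < 0 is leak, lam > 0 instability
    sigma_a2 : accumulator diffusion variance (units^2 per s)
    sigma_s2 : per-pulse amplitude variance (units^2)
    bias     : decision threshold offset in accumulator units
    lapse    : probability of a random (coin-flip) choice, in [0, 1]
    """

    lam: float = 0.0
    sigma_a2: float = 0.0
    sigma_s2: float = 0.0
    bias: float = 0.0
    lapse: float = 0.0

    def __post_init__(self):
        if self.sigma_a2 < 0:
            raise ValueError(f"sigma_a2 must be >= 0, got {self.sigma_a2}")
        if self.sigma_s2 < 0:
            raise ValueError(f"sigma_s2 must be >= 0, got {self.sigma_s2}")
        if not 0.0 <= self.lapse <= 1.0:
            raise ValueError(f"lapse must be in [0, 1], got {self.lapse}")

    def replace(self, **kw) -> "DDMParams":
        return replace(self, **kw)

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.lam, self.sigma_a2, self.sigma_s2, self.bias, self.lapse]
        )

    @staticmethod
    def from_array(x) -> "DDMParams":
        return DDMParams(*(float(v) for v in x))


#: Noise-free ideal observer: a(T) = #R - #L exactly.
IDEAL_PARAMS = DDMParams(0.0, 0.0, 0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GridSpec:
    """Discretization of the accumulator axis.

    spacing    : grid step in accumulator units (grid is symmetric about 0)
    half_width : grid extent; None auto-sizes from the trial and parameters
    """

    spacing: float = 0.02
    half_width: Optional[float] = None


class GridError(RuntimeError):
    """Grid too narrow: probability mass reached the boundary."""


@dataclass
class AccumulatorDistribution:
    """Probability mass of the accumulator over a uniform grid at one time."""

    grid: np.ndarray  # accumulator values, uniform spacing, symmetric about 0
    mass: np.ndarray  # probabilities, same length
    time: float  # s from cue onset

    @property
    def spacing(self) -> float:
        return float(self.grid[1] - self.grid[0])

    def check(self) -> None:
        if np.any(self.mass < -_MASS_TOL):
            raise ValueError("negative probability mass")
        if abs(self.mass.sum() - 1.0) > _MASS_TOL:
            raise ValueError(
                f"mass not conserved: sum = {self.mass.sum():.12f}"
            )

    def mass_above(self, threshold: float) -> float:
        """P(a > threshold) + 0.5 * P(a = threshold).

        Each grid point carries its mass uniformly over the cell
        ``[x - h/2, x + h/2)``; the cell containing the threshold is split
        linearly, so mass exactly at the threshold counts half. This makes
        the left/right mirror antisymmetry exact on a symmetric grid.
        """
        h = self.spacing
        # written as 0.5 + (x - b)/h so the mirror map (x, b) -> (-x, -b)
        # yields exactly complementary cell fractions
        frac = np.clip(0.5 + (self.grid - threshold) / h, 0.0, 1.0)
        return float(np.dot(self.mass, frac))


# ---------------------------------------------------------------------------
# closed-form moments

def _diffusion_variance(lam: float, sigma_a2: float, T) -> np.ndarray:
    """Variance contributed by the dW term over [0, T], exact for any lam."""
    T = np.asarray(T, dtype=float)
    if abs(lam) < 1e-12:
        return sigma_a2 * T
    return sigma_a2 * (np.exp(2.0 * lam * T) - 1.0) / (2.0 * lam)


def _interval_variance(lam: float, sigma_a2: float, delta: float) -> float:
    """Noise variance accrued over one propagation interval of length delta."""
    return float(_diffusion_variance(lam, sigma_a2, delta))


def accumulator_moments(
    trial: Trial, params: DDMParams, t_end: Optional[float] = None
) -> tuple[float, float]:
    """Exact mean and variance of the accumulator at time `t_end`.

    `t_end` defaults to the end of the trial (cue period + delay), the time
    at which the choice is read out.
    """
    T = trial.total_duration if t_end is None else float(t_end)
    lam = params.lam
    mu = 0.0
    var = _interval_variance(lam, params.sigma_a2, T)
    for sign, times in ((1.0, trial.puffs_right), (-1.0, trial.puffs_left)):
        for t in times:
            if t > T:
                continue
            decay = math.exp(lam * (T - t))
            mu += sign * decay
            var += params.sigma_s2 * decay * decay
    return mu, var


# ---------------------------------------------------------------------------
# forward simulation

def _event_times(trial: Trial, dt: float, t_end: float):
    """Merged step boundaries and puff times over [0, t_end].

    Returns (times, puff_signs) where puff_signs[i] is +1/-1 if a puff
    occurs exactly at times[i] (applied on arrival at that time), else 0.
    Simultaneous left+right puffs contribute both amplitudes.
    """
    steps = np.arange(0.0, t_end, dt)
    puffs = [(float(t), +1.0) for t in trial.puffs_right if t <= t_end]
    puffs += [(float(t), -1.0) for t in trial.puffs_left if t <= t_end]
    times = np.unique(np.concatenate(
        [steps, [t_end], [t for t, _ in puffs]]
    ))
    events: dict[float, list[float]] = {}
    for t, s in puffs:
        events.setdefault(t, []).append(s)
    return times, events


def simulate_accumulator(
    trial: Trial,
    params: DDMParams,
    dt: float = 0.015,
    rng: Optional[np.random.Generator] = None,
    n_runs: int = 1,
    t_end: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward-simulate accumulator trajectories.

    Between events the drift is applied with its exact per-interval factor
    ``exp(lam * delta)`` and the diffusion noise with its exact interval
    variance, so the noise-free trajectory is independent of ``dt``; puffs
    are applied at their exact onset times (steps are split at puff times).
    Returns ``(times, a)`` with ``a`` of shape ``(n_runs, len(times))``.
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    rng = np.random.default_rng() if rng is None else rng
    T = trial.total_duration if t_end is None else float(t_end)
    times, events = _event_times(trial, dt, T)
    a = np.zeros((n_runs, len(times)))
    cur = np.zeros(n_runs)
    sigma_s = math.sqrt(params.sigma_s2)
    for i, t in enumerate(times):
        if i > 0:
            delta = t - times[i - 1]
            cur = cur * math.exp(params.lam * delta)
            v = _interval_variance(params.lam, params.sigma_a2, delta)
            if v > 0:
                cur = cur + math.sqrt(v) * rng.standard_normal(n_runs)
        for sign in events.get(float(t), ()):
            if sigma_s > 0:
                eta = 1.0 + sigma_s * rng.standard_normal(n_runs)
            else:
                eta = 1.0
            cur = cur + sign * eta
        a[:, i] = cur
    return times, a


def simulate_endpoints(
    trial: Trial,
    params: DDMParams,
    n_runs: int,
    dt: float = 0.015,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Final accumulator values from `n_runs` forward simulations."""
    _, a = simulate_accumulator(trial, params, dt=dt, rng=rng, n_runs=n_runs)
    return a[:, -1]


# ---------------------------------------------------------------------------
# grid propagation

def _gaussian_kernel(h: float, mean: float, var: float) -> tuple[np.ndarray, int]:
    """Cell-integrated Gaussian kernel on the grid, normalized to sum 1.

    Returns (kernel, offset) where kernel[j] is the mass moved to relative
    grid index ``offset + j``. Cell integration (CDF differences) keeps the
    kernel exact-mass even when the Gaussian is narrow relative to ``h``;
    a zero-variance kernel is a two-point linear split of the shift.
    Kernels are constructed mirror-symmetrically: the zero-mean kernel is
    exactly even, and the kernel for a negative mean is exactly the reverse
    of the positive-mean kernel, so left/right mirror symmetry of the
    propagation is preserved to machine precision.
    """
    if mean < 0:
        k, off = _gaussian_kernel(h, -mean, var)
        return k[::-1].copy(), -(off + len(k) - 1)
    if var <= 0:
        lo = math.floor(mean / h)
        w = mean / h - lo
        if w < 1e-15:
            return np.array([1.0]), lo
        return np.array([1.0 - w, w]), lo
    sd = math.sqrt(var)
    reach = int(math.ceil((8.0 * sd + mean) / h)) + 1
    idx = np.arange(-reach, reach + 1)
    edges = (idx[0] - 0.5 + np.arange(len(idx) + 1)) * h
    cdf = norm.cdf(edges, loc=mean, scale=sd)
    k = np.diff(cdf)
    if mean == 0:
        k = 0.5 * (k + k[::-1])  # enforce exact evenness
    k /= k.sum()
    return k, int(idx[0])


def _convolve(mass: np.ndarray, kernel: np.ndarray, offset: int) -> np.ndarray:
    """Convolve mass with a kernel whose support starts at grid offset.

    Mass that would leave the grid is dropped; callers detect the loss via
    the boundary-mass check.
    """
    n = len(mass)
    full = np.convolve(mass, kernel)
    # full[j] corresponds to grid index j + offset
    out = np.zeros(n)
    start = -offset  # index into full that maps to grid index 0
    lo = max(0, start)
    hi = min(len(full), start + n)
    if lo < hi:
        out[lo - start: hi - start] = full[lo:hi]
    return out


def _rescale_mass(mass: np.ndarray, grid: np.ndarray, c: float) -> np.ndarray:
    """Apply the deterministic drift a -> c*a by mass-conserving splitting.

    Each source point's mass lands at ``c * x`` and is split linearly
    between the two neighboring grid points. Symmetric about 0, so mirror
    symmetry of the distribution is preserved exactly.
    """
    if c == 1.0:
        return mass
    n = len(mass)
    center = n // 2  # grid is symmetric about 0 with odd length
    out = np.zeros_like(mass)
    out[center] = mass[center]
    # work on the positive half and scatter mirror-symmetrically, so the
    # redistribution commutes exactly with grid reversal
    j = np.arange(1, center + 1)
    pos = c * j  # target position in grid units, >= 0
    m = np.floor(pos).astype(int)
    f = pos - m
    for tgt, wgt in ((m, 1.0 - f), (m + 1, f)):
        ok = tgt <= center
        np.add.at(out, center + tgt[ok], mass[center + j[ok]] * wgt[ok])
        np.add.at(out, center - tgt[ok], mass[center - j[ok]] * wgt[ok])
    return out


def auto_half_width(trial: Trial, params: DDMParams, t_end: float) -> float:
    """Grid extent covering the puff sum, 6 sigma of noise, and the bias."""
    n_puffs = len(trial.puffs_left) + len(trial.puffs_right)
    growth = math.exp(max(params.lam, 0.0) * t_end)
    _, var = accumulator_moments(trial, params, t_end=t_end)
    return (
        n_puffs * growth
        + 6.0 * math.sqrt(max(var, 0.0))
        + abs(params.bias)
        + 2.0
    )


def propagate_distribution(
    trial: Trial,
    params: DDMParams,
    grid: Optional[GridSpec] = None,
    dt: float = 0.015,
    t_end: Optional[float] = None,
) -> AccumulatorDistribution:
    """Propagate the accumulator probability mass to the end of the trial.

    Starts from a delta at 0. Each interval between successive time points
    (step boundaries split at puff times) applies the deterministic drift
    ``a -> a * exp(lam * delta)`` by mass-conserving two-point redistribution,
    then convolves with the interval's diffusion noise; each puff convolves
    with ``N(+/-1, sigma_s2)`` (a pure two-point shift when ``sigma_s2 = 0``).

    Raises :class:`GridError` if mass reaches the grid boundary (never
    silently truncates).
    """
    if dt <= 0:
        raise ValueError(f"dt must be positive, got {dt}")
    T = trial.total_duration if t_end is None else float(t_end)
    spec = grid or GridSpec()
    h = spec.spacing
    half = spec.half_width or auto_half_width(trial, params, T)
    n_half = int(math.ceil(half / h))
    x = np.arange(-n_half, n_half + 1) * h  # symmetric, odd length, 0 at center

    mass = np.zeros(len(x))
    mass[n_half] = 1.0

    times, events = _event_times(trial, dt, T)
    for i, t in enumerate(times):
        if i > 0:
            delta = t - times[i - 1]
            c = math.exp(params.lam * delta)
            mass = _rescale_mass(mass, x, c)
            v = _interval_variance(params.lam, params.sigma_a2, delta)
            if v > 0:
                k, off = _gaussian_kernel(h, 0.0, v)
                mass = _convolve(mass, k, off)
        for sign in events.get(float(t), ()):
            k, off = _gaussian_kernel(h, sign * 1.0, params.sigma_s2)
            mass = _convolve(mass, k, off)
        total = mass.sum()
        edge = mass[0] + mass[-1] + (1.0 - total)
        if edge > _BOUNDARY_TOL:
            raise GridError(
                f"grid half-width {half:.2f} too narrow at t={t:.3f}s: "
                f"boundary mass {edge:.3g} exceeds {_BOUNDARY_TOL:g}"
            )
        # restore unit mass after verified sub-tolerance tail truncation
        mass /= total
    dist = AccumulatorDistribution(grid=x, mass=mass, time=T)
    dist.check()
    return dist


# ---------------------------------------------------------------------------
# choice probability and likelihood

def _apply_lapse(p_above: float, lapse: float) -> float:
    return 0.5 * lapse + (1.0 - lapse) * p_above


def choice_probability(
    dist: AccumulatorDistribution, params: DDMParams
) -> float:
    """P(rightward choice) from a propagated accumulator distribution.

    ``P = 0.5*lapse + (1 - lapse) * [P(a > bias) + 0.5 * P(a = bias)]``;
    the cell containing the threshold is split by linear interpolation.
    """
    return _apply_lapse(dist.mass_above(params.bias), params.lapse)


def choice_probability_analytic(trial: Trial, params: DDMParams) -> float:
    """P(rightward choice) from the exact Gaussian closed form."""
    mu, var = accumulator_moments(trial, params)
    if var <= 0:
        d = mu - params.bias
        p_above = 0.5 if d == 0 else (1.0 if d > 0 else 0.0)
    else:
        p_above = float(norm.sf((params.bias - mu) / math.sqrt(var)))
    return _apply_lapse(p_above, params.lapse)


_LOG_FLOOR = math.log(np.finfo(float).tiny)


def trial_loglik(
    trial: Trial,
    choice: str,
    params: DDMParams,
    grid: Optional[GridSpec] = None,
    dt: float = 0.015,
    engine: str = "analytic",
) -> float:
    """Log-probability of the observed choice under the model.

    ``engine="analytic"`` uses the exact Gaussian closed form (default);
    ``engine="grid"`` propagates the discretized distribution. Both floor
    the log at the machine-tiny boundary.
    """
    if choice not in ("left", "right"):
        raise ValueError(f"choice must be left or right, got {choice!r}")
    if engine == "grid":
        p_right = choice_probability(
            propagate_distribution(trial, params, grid=grid, dt=dt), params
        )
    elif engine == "analytic":
        p_right = choice_probability_analytic(trial, params)
    else:
        raise ValueError(f"unknown engine {engine!r}")
    p = p_right if choice == "right" else 1.0 - p_right
    return math.log(p) if p > np.finfo(float).tiny else _LOG_FLOOR


def dataset_loglik(
    trials,
    params: DDMParams,
    grid: Optional[GridSpec] = None,
    dt: float = 0.015,
    engine: str = "analytic",
    cue_filter: Optional[float] = 3.8,
) -> tuple[float, int]:
    """Total log-likelihood over included trials.

    Included: decision-made (choice != none), non-guided trials, and --
    matching the analysis filters -- only the primary cue duration when
    ``cue_filter`` is set (pass None to include all cue durations).
    Returns ``(lnL, n_excluded)``.
    """
    total = 0.0
    n_inc = 0
    n_exc = 0
    for t in trials:
        if (
            t.choice == "none"
            or t.guided
            or (cue_filter is not None and abs(t.cue_duration - cue_filter) > 1e-6)
        ):
            n_exc += 1
            continue
        total += trial_loglik(t, t.choice, params, grid=grid, dt=dt, engine=engine)
        n_inc += 1
    if n_inc == 0:
        raise ValueError("no trials included in the likelihood")
    return total, n_exc


@dataclass(frozen=True)
class TimeConstant:
    """Memory time constant tau = 1/|lambda| with a leak/instability label."""

    tau: float  # seconds; inf when lambda = 0
    label: str  # "leaky" | "unstable" | "non-leaky"


def tau_from_lambda(lam: float) -> TimeConstant:
    """Decay time constant of accumulated evidence.

    Reported as ``1/|lambda|`` with the regime labeled by the sign of
    ``lambda`` (positive time constants are quoted for leaky memory).
    """
    if lam == 0:
        return TimeConstant(tau=math.inf, label="non-leaky")
    return TimeConstant(
        tau=1.0 / abs(lam), label="leaky" if lam < 0 else "unstable"
    )
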