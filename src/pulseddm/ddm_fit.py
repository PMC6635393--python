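"""Maximum-likelihood fitting of the pulse accumulator.

The fitting protocol mirrors the study's: each model variant is fit many
times (default 1000; a 50-repetition test profile is used by the bundled
experiments), each repetition drawing random initial parameters and omitting
a random 20% of trials; a repetition is accepted only if the optimizer
converged and the Hessian of the negative log-likelihood at the optimum is
positive semidefinite. Medians and quantiles across accepted repetitions
summarize the fit, and held-out choice-prediction accuracy (predict right
when p(R|theta) > 0.5) provides a cross-validated goodness-of-fit measure.

Optimization runs in unconstrained internal coordinates (lambda and bias
free, variances through ``floor + exp(theta)``, lapse through a logistic
map) with numerical gradients. The likelihood is evaluated through the
exact Gaussian closed form (see :mod:`pulseddm.ddm_core`), vectorized over
trials.

Model comparison uses the score ``BIC = ln L - k ln(n) / 2``, under which
larger values indicate a favored model; ``relative_bic`` reports a variant's
score minus the full model's, positive favoring the variant.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import optimize
from scipy.stats import norm

from .ddm_core import DDMParams
from .trial_io import TrialSet

__all__ = [
    "ModelVariant",
    "FULL_MODEL",
    "NO_LAPSE",
    "NO_BIAS",
    "FitResult",
    "TrialMatrix",
    "fit_once",
    "fit_ddm",
    "hessian_psd_check",
    "numerical_hessian",
    "cv_choice_accuracy",
    "bic",
    "relative_bic",
    "DEFAULT_INIT_RANGES",
]

#: Positivity floor for the variance parameters.
VARIANCE_FLOOR = 1e-6

#: Uniform ranges for random initial parameter draws.
DEFAULT_INIT_RANGES = {
    "lam": (-5.0, 5.0),
    "sigma_a2": (0.0, 20.0),
    "sigma_s2": (0.0, 20.0),
    "bias": (-3.0, 3.0),
    "lapse": (0.0, 1.0),
}

_PARAM_NAMES = ("lam", "sigma_a2", "sigma_s2", "bias", "lapse")


@dataclass(frozen=True)
class ModelVariant:
    """Which optional parameters are fit; omitted ones are fixed at 0."""

    name: str = "full"
    fit_bias: bool = True
    fit_lapse: bool = True

    @property
    def k(self) -> int:
        return 3 + int(self.fit_bias) + int(self.fit_lapse)

    @property
    def free_names(self) -> tuple[str, ...]:
        names = ["lam", "sigma_a2", "sigma_s2"]
        if self.fit_bias:
            names.append("bias")
        if self.fit_lapse:
            names.append("lapse")
        return tuple(names)


FULL_MODEL = ModelVariant("full", fit_bias=True, fit_lapse=True)
NO_LAPSE = ModelVariant("no-lapse", fit_bias=True, fit_lapse=False)
NO_BIAS = ModelVariant("no-bias", fit_bias=False, fit_lapse=True)


class TrialMatrix:
    """Padded per-trial puff arrays for vectorized likelihood evaluation.

    Applies the analysis inclusion filters once (decision made, non-guided,
    and -- unless ``cue_filter=None`` -- the primary cue duration), then
    stores, per trial, the times-to-trial-end of every puff and its sign.
    """

    def __init__(self, trials: TrialSet, cue_filter: Optional[float] = 3.8):
        kept = []
        for t in trials:
            if t.choice == "none" or t.guided:
                continue
            if cue_filter is not None and abs(t.cue_duration - cue_filter) > 1e-6:
                continue
            kept.append(t)
        self.n_excluded = len(trials) - len(kept)
        self.n = len(kept)
        if self.n == 0:
            raise ValueError("no trials pass the inclusion filters")
        m = max(len(t.puffs_left) + len(t.puffs_right) for t in kept)
        self.tau = np.zeros((self.n, m))
        self.sign = np.zeros((self.n, m))
        self.T = np.array([t.total_duration for t in kept])
        self.y = np.array([t.choice == "right" for t in kept])
        for i, t in enumerate(kept):
            j = 0
            for s, times in ((1.0, t.puffs_right), (-1.0, t.puffs_left)):
                for tt in times:
                    self.tau[i, j] = t.total_duration - tt
                    self.sign[i, j] = s
                    j += 1
        self.mask = self.sign != 0.0
        self._cache_lam: Optional[float] = None
        self._cache: Optional[tuple] = None

    def _lam_terms(self, lam: float):
        # numerical gradients perturb one parameter at a time, so most
        # objective calls reuse the exponentials from the previous lambda
        if self._cache_lam == lam:
            return self._cache
        E = np.where(self.mask, np.exp(lam * self.tau), 0.0)
        mu_unit = (self.sign * E).sum(axis=1)
        e2_sum = (E * E).sum(axis=1)
        if abs(lam) < 1e-12:
            g = self.T.copy()
        else:
            g = (np.exp(2.0 * lam * self.T) - 1.0) / (2.0 * lam)
        self._cache_lam = lam
        self._cache = (mu_unit, e2_sum, g)
        return self._cache

    def p_right(self, params: DDMParams) -> np.ndarray:
        """P(rightward choice) for every trial, exact closed form."""
        mu, e2_sum, g = self._lam_terms(params.lam)
        var = params.sigma_s2 * e2_sum + params.sigma_a2 * g
        var = np.maximum(var, 1e-30)
        p_above = norm.sf((params.bias - mu) / np.sqrt(var))
        return 0.5 * params.lapse + (1.0 - params.lapse) * p_above

    def loglik(self, params: DDMParams) -> float:
        p = self.p_right(params)
        p_obs = np.where(self.y, p, 1.0 - p)
        tiny = np.finfo(float).tiny
        return float(np.sum(np.log(np.maximum(p_obs, tiny))))

    def loglik_grad(self, params: DDMParams) -> tuple[float, np.ndarray]:
        """Log-likelihood and its exact gradient on the natural scale.

        Gradient order: (lam, sigma_a2, sigma_s2, bias, lapse). Derived by
        differentiating the Gaussian closed form; validated against central
        differences in the test suite.
        """
        lam, a2, s2 = params.lam, params.sigma_a2, params.sigma_s2
        bias, lapse = params.bias, params.lapse
        E = np.where(self.mask, np.exp(lam * self.tau), 0.0)
        tauE = self.tau * E
        mu = (self.sign * E).sum(axis=1)
        dmu = (self.sign * tauE).sum(axis=1)
        e2 = (E * E).sum(axis=1)
        de2 = 2.0 * (tauE * E).sum(axis=1)
        if abs(lam) < 1e-12:
            g = self.T.copy()
            dg = self.T**2
        else:
            e2T = np.exp(2.0 * lam * self.T)
            g = (e2T - 1.0) / (2.0 * lam)
            dg = self.T * e2T / lam - (e2T - 1.0) / (2.0 * lam * lam)
        var = np.maximum(s2 * e2 + a2 * g, 1e-30)
        sd = np.sqrt(var)
        d = (bias - mu) / sd
        sf = norm.sf(d)
        pdf = norm.pdf(d)
        p = 0.5 * lapse + (1.0 - lapse) * sf
        p_obs = np.where(self.y, p, 1.0 - p)
        tiny = np.finfo(float).tiny
        ll = float(np.sum(np.log(np.maximum(p_obs, tiny))))

        sgn = np.where(self.y, 1.0, -1.0)
        dL_dp = sgn / np.maximum(p_obs, tiny)
        # P(right) = 0.5*lapse + (1 - lapse) * sf(d)
        dp_dd = -(1.0 - lapse) * pdf
        dd_dvar = -d / (2.0 * var)
        common = dL_dp * dp_dd
        grad = np.array([
            float(np.sum(common * (-dmu / sd + dd_dvar * (s2 * de2 + a2 * dg)))),
            float(np.sum(common * dd_dvar * g)),
            float(np.sum(common * dd_dvar * e2)),
            float(np.sum(common / sd)),
            float(np.sum(dL_dp * (0.5 - sf))),
        ])
        return ll, grad

    def subset(self, idx: np.ndarray) -> "TrialMatrix":
        sub = object.__new__(TrialMatrix)
        sub.n_excluded = 0
        sub.n = len(idx)
        sub.tau = self.tau[idx]
        sub.sign = self.sign[idx]
        sub.mask = self.mask[idx]
        sub.T = self.T[idx]
        sub.y = self.y[idx]
        sub._cache_lam = None
        sub._cache = None
        return sub


# ---------------------------------------------------------------------------
# parameter transforms (unconstrained internal coordinates)

def _to_internal(params: DDMParams, variant: ModelVariant) -> np.ndarray:
    theta = [
        params.lam,
        math.log(max(params.sigma_a2 - VARIANCE_FLOOR, 1e-12)),
        math.log(max(params.sigma_s2 - VARIANCE_FLOOR, 1e-12)),
    ]
    if variant.fit_bias:
        theta.append(params.bias)
    if variant.fit_lapse:
        p = min(max(params.lapse, 1e-12), 1.0 - 1e-12)
        theta.append(math.log(p / (1.0 - p)))
    return np.array(theta)


def _from_internal(theta: np.ndarray, variant: ModelVariant) -> DDMParams:
    lam = float(theta[0])
    sigma_a2 = VARIANCE_FLOOR + math.exp(float(theta[1]))
    sigma_s2 = VARIANCE_FLOOR + math.exp(float(theta[2]))
    i = 3
    bias = 0.0
    lapse = 0.0
    if variant.fit_bias:
        bias = float(theta[i])
        i += 1
    if variant.fit_lapse:
        lapse = 1.0 / (1.0 + math.exp(-float(theta[i])))
    return DDMParams(lam, sigma_a2, sigma_s2, bias, lapse)


def _internal_bounds(variant: ModelVariant) -> list[tuple[float, float]]:
    bounds = [(-10.0, 10.0), (-30.0, 5.0), (-30.0, 5.0)]
    if variant.fit_bias:
        bounds.append((-10.0, 10.0))
    if variant.fit_lapse:
        bounds.append((-20.0, 20.0))
    return bounds


def draw_init(
    rng: np.random.Generator,
    ranges: Optional[dict] = None,
) -> DDMParams:
    """Random initial parameters, uniform over the configured ranges."""
    r = dict(DEFAULT_INIT_RANGES)
    if ranges:
        r.update(ranges)
    vals = {name: float(rng.uniform(*r[name])) for name in _PARAM_NAMES}
    vals["sigma_a2"] = max(vals["sigma_a2"], 2 * VARIANCE_FLOOR)
    vals["sigma_s2"] = max(vals["sigma_s2"], 2 * VARIANCE_FLOOR)
    vals["lapse"] = min(max(vals["lapse"], 1e-6), 1.0 - 1e-6)
    return DDMParams(**vals)


# ---------------------------------------------------------------------------
# single fit

def fit_once(
    trials,
    variant: ModelVariant = FULL_MODEL,
    init: Optional[DDMParams] = None,
    rng: Optional[np.random.Generator] = None,
    cue_filter: Optional[float] = 3.8,
    min_trials: int = 100,
    max_init_retries: int = 10,
    maxiter: int = 300,
) -> tuple[DDMParams, float, bool]:
    """One gradient-based maximization of the dataset log-likelihood.

    `trials` may be a TrialSet or a prebuilt :class:`TrialMatrix`. Returns
    ``(params, lnL, converged)`` on the natural parameter scale. A
    non-finite likelihood at the starting point triggers a bounded number of
    re-drawn initializations.
    """
    mat = trials if isinstance(trials, TrialMatrix) else TrialMatrix(trials, cue_filter)
    if mat.n < min_trials:
        raise ValueError(
            f"need at least {min_trials} included trials, got {mat.n}"
        )
    rng = np.random.default_rng() if rng is None else rng
    if init is None:
        init = draw_init(rng)

    def objective(theta: np.ndarray) -> tuple[float, np.ndarray]:
        params = _from_internal(theta, variant)
        with np.errstate(over="ignore", invalid="ignore"):
            ll, g = mat.loglik_grad(params)
        if not np.isfinite(ll):
            return 1e300, np.zeros(len(theta))
        # chain rule from natural scale to internal coordinates
        gi = [
            g[0],
            g[1] * (params.sigma_a2 - VARIANCE_FLOOR),
            g[2] * (params.sigma_s2 - VARIANCE_FLOOR),
        ]
        if variant.fit_bias:
            gi.append(g[3])
        if variant.fit_lapse:
            gi.append(g[4] * params.lapse * (1.0 - params.lapse))
        gi = np.nan_to_num(np.asarray(gi), nan=0.0, posinf=0.0, neginf=0.0)
        return -ll, -gi

    theta0 = _to_internal(init, variant)
    for _ in range(max_init_retries):
        if objective(theta0)[0] < 1e300:
            break
        theta0 = _to_internal(draw_init(rng), variant)
    else:
        return init, -math.inf, False

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        jac=True,
        bounds=_internal_bounds(variant),
        options={"maxiter": maxiter},
    )
    params = _from_internal(res.x, variant)
    return params, -float(res.fun), bool(res.success)


def _fit_best(
    mat: TrialMatrix,
    variant: ModelVariant,
    rng: np.random.Generator,
    init_ranges: Optional[dict],
    n_candidates: int = 8,
    n_optimize: int = 2,
) -> tuple[Optional[DDMParams], float]:
    """One repetition's fit: screen random inits, optimize from the best few.

    The likelihood surface has a flat coin-flip plateau (lapse -> 1 or very
    large noise) on which gradient ascent from a poor start can stall, so
    each repetition draws several candidate initializations, ranks them by
    their starting log-likelihood, runs the optimizer from the top few, and
    keeps the converged result with the highest likelihood.
    """
    cands = [draw_init(rng, init_ranges) for _ in range(n_candidates)]
    scored = sorted(
        ((mat.loglik(c), c) for c in cands), key=lambda t: t[0], reverse=True
    )
    best, best_lnl = None, -math.inf
    for score, init in scored[:n_optimize]:
        if not np.isfinite(score):
            continue
        params, lnl, converged = fit_once(
            mat, variant, init=init, rng=rng, min_trials=1
        )
        if converged and lnl > best_lnl:
            best, best_lnl = params, lnl
    return best, best_lnl


# ---------------------------------------------------------------------------
# Hessian acceptance filter

def numerical_hessian(
    f: Callable[[np.ndarray], float],
    x: np.ndarray,
    steps: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Central-difference Hessian of a scalar function."""
    x = np.asarray(x, dtype=float)
    d = len(x)
    if steps is None:
        steps = np.maximum(1e-3 * np.abs(x), 1e-4)
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            hi, hj = steps[i], steps[j]
            if i == j:
                val = (f(x + _e(d, i, hi)) - 2.0 * f(x) + f(x - _e(d, i, hi))) / (hi * hi)
            else:
                val = (
                    f(x + _e(d, i, hi) + _e(d, j, hj))
                    - f(x + _e(d, i, hi) - _e(d, j, hj))
                    - f(x - _e(d, i, hi) + _e(d, j, hj))
                    + f(x - _e(d, i, hi) - _e(d, j, hj))
                ) / (4.0 * hi * hj)
            H[i, j] = H[j, i] = val
    return H


def _e(d: int, i: int, h: float) -> np.ndarray:
    v = np.zeros(d)
    v[i] = h
    return v


def hessian_psd_check(
    params: DDMParams,
    trials,
    variant: ModelVariant = FULL_MODEL,
    cue_filter: Optional[float] = 3.8,
    tol: float = 1e-6,
) -> bool:
    """True iff the negative log-likelihood Hessian at `params` is PSD.

    The Hessian is taken on the natural parameter scale by central
    differences, and the check is ``smallest eigenvalue >= -tol * largest
    eigenvalue``. Parameters pinned at a constraint boundary (variances at
    the positivity floor, lapse at 0 or 1) are excluded: at a boundary
    optimum the curvature along the constrained direction is one-sided and
    the PSD condition applies to the interior directions only. Non-finite
    Hessian entries fail the check.
    """
    mat = trials if isinstance(trials, TrialMatrix) else TrialMatrix(trials, cue_filter)
    names = list(variant.free_names)
    x0 = np.array([getattr(params, n) for n in names])
    steps = np.maximum(1e-3 * np.abs(x0), 1e-4)

    # drop directions whose +/- step would leave the valid domain
    interior = []
    for i, name in enumerate(names):
        v = x0[i]
        if name in ("sigma_a2", "sigma_s2") and v - steps[i] < 0:
            continue
        if name == "lapse" and (v - steps[i] < 0 or v + steps[i] > 1):
            continue
        interior.append(i)
    if not interior:
        return True
    names = [names[i] for i in interior]
    x0 = x0[interior]
    steps = steps[interior]

    def nll(x: np.ndarray) -> float:
        vals = {
            "lam": params.lam,
            "sigma_a2": params.sigma_a2,
            "sigma_s2": params.sigma_s2,
            "bias": params.bias,
            "lapse": params.lapse,
        }
        vals.update(zip(names, x))
        return -mat.loglik(DDMParams(**vals))

    H = numerical_hessian(nll, x0, steps=steps)
    if not np.all(np.isfinite(H)):
        return False
    eigs = np.linalg.eigvalsh(H)
    return bool(eigs.min() >= -tol * max(eigs.max(), 1.0))


# ---------------------------------------------------------------------------
# repetition protocol

@dataclass
class FitResult:
    """Summary of a multi-repetition fitting run for one model variant."""

    variant: ModelVariant
    params_reps: np.ndarray  # (n_accepted, 5) natural-scale parameter vectors
    lnl_reps: np.ndarray  # training lnL per accepted repetition
    cv_accuracy_reps: np.ndarray  # held-out accuracy per accepted repetition
    n_reps: int
    n_accepted: int
    n_trials: int
    lnl_full: float  # lnL on all included trials at the median parameters

    @property
    def params_median(self) -> DDMParams:
        return DDMParams.from_array(np.median(self.params_reps, axis=0))

    def quantiles(self, q: Sequence[float] = (0.025, 0.975)) -> dict:
        out = {}
        for i, name in enumerate(_PARAM_NAMES):
            col = self.params_reps[:, i]
            out[name] = {
                "median": float(np.median(col)),
                **{f"q{100 * qq:g}": float(np.quantile(col, qq)) for qq in q},
            }
        return out

    @property
    def cv_accuracy(self) -> float:
        return float(np.mean(self.cv_accuracy_reps))

    @property
    def cv_accuracy_sd(self) -> float:
        return float(np.std(self.cv_accuracy_reps))

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.name,
            "k": self.variant.k,
            "n_trials": self.n_trials,
            "n_reps": self.n_reps,
            "n_accepted": self.n_accepted,
            "parameters": self.quantiles(),
            "cv_accuracy": {"mean": self.cv_accuracy, "sd": self.cv_accuracy_sd},
            "lnl_full": self.lnl_full,
            "bic": bic(self.lnl_full, self.variant.k, self.n_trials),
            "bic_convention": "lnL - k*ln(n)/2; larger favored",
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def _predict_accuracy(mat: TrialMatrix, params: DDMParams) -> float:
    # exactly 0.5 counts as a rightward prediction (documented tie rule)
    pred_right = mat.p_right(params) >= 0.5
    return float(np.mean(pred_right == mat.y))


def fit_ddm(
    trials,
    variant: ModelVariant = FULL_MODEL,
    n_reps: int = 1000,
    holdout: float = 0.2,
    rng: Optional[np.random.Generator] = None,
    cue_filter: Optional[float] = 3.8,
    min_trials: int = 100,
    init_ranges: Optional[dict] = None,
    check_hessian: bool = True,
) -> FitResult:
    """Repetition-based ML fit with random inits and trial subsampling.

    Each repetition omits a random ``holdout`` fraction of trials, fits the
    remainder from a fresh random initialization, and is accepted only if
    the optimizer converged and (when ``check_hessian``) the Hessian at the
    optimum is positive semidefinite. Held-out trials provide the
    cross-validated choice-prediction accuracy of that repetition.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    if not 0.0 <= holdout < 1.0:
        raise ValueError(f"holdout must be in [0, 1), got {holdout}")
    rng = np.random.default_rng() if rng is None else rng
    mat = trials if isinstance(trials, TrialMatrix) else TrialMatrix(trials, cue_filter)
    if mat.n < min_trials:
        raise ValueError(f"need at least {min_trials} included trials, got {mat.n}")

    n_hold = int(round(holdout * mat.n))
    kept_params, kept_lnl, kept_acc = [], [], []
    diagnostics = {"not_converged": 0, "hessian_rejected": 0}
    for _ in range(n_reps):
        perm = rng.permutation(mat.n)
        fit_idx = perm[n_hold:]
        hold_idx = perm[:n_hold]
        fit_mat = mat.subset(fit_idx)
        params, lnl = _fit_best(fit_mat, variant, rng, init_ranges)
        if params is None:
            diagnostics["not_converged"] += 1
            continue
        if check_hessian and not hessian_psd_check(params, fit_mat, variant):
            diagnostics["hessian_rejected"] += 1
            continue
        kept_params.append(params.as_array())
        kept_lnl.append(lnl)
        if n_hold > 0:
            kept_acc.append(_predict_accuracy(mat.subset(hold_idx), params))
        else:
            kept_acc.append(_predict_accuracy(fit_mat, params))
    if not kept_params:
        raise RuntimeError(
            f"no accepted fit repetitions out of {n_reps}: {diagnostics}"
        )
    result = FitResult(
        variant=variant,
        params_reps=np.array(kept_params),
        lnl_reps=np.array(kept_lnl),
        cv_accuracy_reps=np.array(kept_acc),
        n_reps=n_reps,
        n_accepted=len(kept_params),
        n_trials=mat.n,
        lnl_full=0.0,
    )
    result.lnl_full = mat.loglik(result.params_median)
    return result


def cv_choice_accuracy(
    train,
    test,
    variant: ModelVariant = FULL_MODEL,
    rng: Optional[np.random.Generator] = None,
    n_restarts: int = 3,
    cue_filter: Optional[float] = 3.8,
) -> float:
    """Fit on `train`, then fraction of `test` choices predicted correctly.

    Prediction thresholds p(R|theta) at 0.5 (exactly 0.5 counts as right).
    """
    rng = np.random.default_rng() if rng is None else rng
    train_mat = train if isinstance(train, TrialMatrix) else TrialMatrix(train, cue_filter)
    test_mat = test if isinstance(test, TrialMatrix) else TrialMatrix(test, cue_filter)
    if test_mat.n == 0:
        raise ValueError("empty test set")
    best, _ = _fit_best(
        train_mat, variant, rng, None, n_optimize=max(n_restarts, 1)
    )
    if best is None:
        raise RuntimeError("no converged fit on the training set")
    return _predict_accuracy(test_mat, best)


# ---------------------------------------------------------------------------
# model comparison

def bic(lnl: float, k: int, n: int) -> float:
    """Model-comparison score ``ln L - k ln(n) / 2`` (larger is better)."""
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    return lnl - 0.5 * k * math.log(n)


def relative_bic(variant_lnl: float, variant_k: int,
                 full_lnl: float, full_k: int, n: int) -> float:
    """Variant score minus full-model score; positive favors the variant."""
    return bic(variant_lnl, variant_k, n) - bic(full_lnl, full_k, n)
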