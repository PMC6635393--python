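"""Performance summaries, psychometric curve fitting, and condition contrasts.

Performance is the fraction of decision-made trials in which the choice
matched the side with more puffs, with binomial confidence intervals by the
Jeffreys method (central quantiles of a Beta(k + 1/2, n - k + 1/2)
reference, with the standard boundary convention that the interval touches
0 when k = 0 and 1 when k = n). The psychometric curve is the four-parameter
logistic

    y(x) = y0 + A / (1 + exp(-(x - x0) / b))

of right-choice probability against the signed evidence strength
x = #R - #L, fit by count-weighted least squares over pooled trials.
Guided trials are excluded from psychometrics (they are rewarded regardless
of choice) and summarized separately as a response-capability control.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import beta as beta_dist
from scipy.stats import ttest_rel

__all__ = [
    "PerformanceSummary",
    "PsychometricFit",
    "ConditionContrast",
    "jeffreys_interval",
    "performance_summary",
    "choice_matrix",
    "fit_psychometric",
    "compare_conditions",
]


@dataclass(frozen=True)
class PerformanceSummary:
    """Fraction correct over decision-made trials with a Jeffreys CI."""

    n: int  # decision-made trials
    k: int  # correct among them
    fraction: float
    ci_level: float
    ci_low: float
    ci_high: float
    response_fraction: float  # decision-made / total trials


@dataclass(frozen=True)
class PsychometricFit:
    """Four-parameter logistic psychometric curve.

    y0 : lower asymptote; A : range; x0 : midpoint (puffs);
    b  : slope scale (puffs). ``cov`` is the parameter covariance from the
    fit (None when the curve was constructed directly).
    """

    y0: float
    A: float
    x0: float
    b: float
    cov: Optional[np.ndarray] = None

    def prob_right(self, delta) -> np.ndarray:
        x = np.asarray(delta, dtype=float)
        y = self.y0 + self.A / (1.0 + np.exp(-(x - self.x0) / self.b))
        return np.clip(y, 0.0, 1.0)

    @property
    def se(self) -> Optional[np.ndarray]:
        if self.cov is None:
            return None
        return np.sqrt(np.diag(self.cov))


@dataclass(frozen=True)
class ConditionContrast:
    """Paired light-on minus light-off performance contrast across subjects."""

    subjects: tuple[str, ...]
    delta: np.ndarray  # per-subject on - off fraction correct
    mean_delta: float
    t_statistic: float
    p_value: float


def jeffreys_interval(k: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Jeffreys binomial interval: Beta(k + 1/2, n - k + 1/2) quantiles.

    The lower bound is 0 when k = 0 and the upper bound is 1 when k = n.
    """
    if not 0 <= k <= n or n < 1:
        raise ValueError(f"need 0 <= k <= n with n >= 1, got k={k}, n={n}")
    alpha = 1.0 - level
    lo = 0.0 if k == 0 else float(beta_dist.ppf(alpha / 2, k + 0.5, n - k + 0.5))
    hi = 1.0 if k == n else float(beta_dist.ppf(1 - alpha / 2, k + 0.5, n - k + 0.5))
    return lo, hi


def performance_summary(trials, ci_level: float = 0.95) -> PerformanceSummary:
    """Fraction of correct choices among decision-made, non-guided trials."""
    total = 0
    n = 0
    k = 0
    for t in trials:
        if t.guided:
            continue
        total += 1
        if t.choice == "none":
            continue
        n += 1
        k += int(t.choice == t.correct_side)
    if n == 0:
        raise ValueError("no decision-made trials")
    lo, hi = jeffreys_interval(k, n, ci_level)
    return PerformanceSummary(
        n=n, k=k, fraction=k / n, ci_level=ci_level, ci_low=lo, ci_high=hi,
        response_fraction=n / total,
    )


def choice_matrix(trials) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Right-choice probability and trial counts per (#L, #R) cell.

    Returns ``(p_right, counts)`` DataFrames indexed by #L (rows) and #R
    (columns); cells with no trials hold NaN probability and zero count.
    """
    rows = [
        (t.n_left, t.n_right, t.choice == "right")
        for t in trials
        if t.choice != "none" and not t.guided
    ]
    if not rows:
        empty = pd.DataFrame()
        return empty, empty
    df = pd.DataFrame(rows, columns=["n_left", "n_right", "right"])
    grouped = df.groupby(["n_left", "n_right"])["right"]
    counts = grouped.count().unstack(fill_value=0)
    p = grouped.mean().unstack()
    # square index/columns over the full observed range
    all_l = range(int(df.n_left.min()), int(df.n_left.max()) + 1)
    all_r = range(int(df.n_right.min()), int(df.n_right.max()) + 1)
    counts = counts.reindex(index=all_l, columns=all_r, fill_value=0)
    p = p.reindex(index=all_l, columns=all_r)
    return p, counts


def fit_psychometric(trials, maxfev: int = 20000) -> PsychometricFit:
    """Count-weighted least-squares fit of the four-parameter logistic.

    The right-choice fraction at each observed evidence strength
    x = #R - #L is fit with weights proportional to the per-x trial count.
    Requires at least 4 distinct x values with decisions.
    """
    deltas, choices = [], []
    for t in trials:
        if t.choice == "none" or t.guided:
            continue
        deltas.append(t.delta)
        choices.append(t.choice == "right")
    if not deltas:
        raise ValueError("no decision-made trials")
    df = pd.DataFrame({"x": deltas, "right": choices})
    grouped = df.groupby("x")["right"].agg(["mean", "count"]).reset_index()
    x = grouped["x"].to_numpy(dtype=float)
    frac = grouped["mean"].to_numpy(dtype=float)
    n = grouped["count"].to_numpy(dtype=float)
    if len(x) < 4:
        raise ValueError(
            f"need >= 4 distinct evidence values, got {len(x)}"
        )

    def model(xx, y0, A, x0, b):
        return y0 + A / (1.0 + np.exp(-(xx - x0) / b))

    span = float(x.max() - x.min())
    p0 = [max(frac.min(), 0.0), max(frac.max() - frac.min(), 0.1), 0.0, max(span / 8, 0.5)]
    bounds = ([-0.5, 0.0, x.min() - span, 1e-3], [1.0, 1.5, x.max() + span, 10 * span])
    try:
        popt, pcov = optimize.curve_fit(
            model, x, frac, p0=p0, sigma=1.0 / np.sqrt(n),
            absolute_sigma=False, bounds=bounds, maxfev=maxfev,
        )
    except RuntimeError as e:
        raise RuntimeError(
            f"psychometric fit did not converge on {len(x)} evidence levels "
            f"spanning [{x.min():g}, {x.max():g}]: {e}"
        ) from e
    return PsychometricFit(
        y0=float(popt[0]), A=float(popt[1]), x0=float(popt[2]), b=float(popt[3]),
        cov=pcov,
    )


def compare_conditions(off: dict, on: dict) -> ConditionContrast:
    """Paired two-tailed t-test on per-subject performance changes.

    `off` and `on` map subject id to a :class:`PerformanceSummary` (or any
    object with a ``fraction`` attribute); subject sets must match and hold
    at least 2 subjects.
    """
    if set(off) != set(on):
        raise ValueError(
            f"subject mismatch: off={sorted(off)} vs on={sorted(on)}"
        )
    subjects = tuple(sorted(off))
    if len(subjects) < 2:
        raise ValueError("need >= 2 matched subjects")
    f_off = np.array([off[s].fraction for s in subjects])
    f_on = np.array([on[s].fraction for s in subjects])
    delta = f_on - f_off
    t, p = ttest_rel(f_on, f_off)
    return ConditionContrast(
        subjects=subjects, delta=delta, mean_delta=float(delta.mean()),
        t_statistic=float(t), p_value=float(p),
    )
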