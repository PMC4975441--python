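"""Profile-likelihood confidence intervals and the sigma approximation.

The profile of a parameter is obtained by fixing it on a grid around the
maximum-likelihood estimate and re-optimizing all remaining parameters at
each value (adaptive stepping, targeting a fixed objective rise per step).
Crossings of the threshold level Delta above the optimum define the
confidence interval; following the reporting convention "factor +/- sigma",
sigma is approximated conservatively by the larger of the two log10
distances between the estimate and the interval limits.  Delta = 1
corresponds to a pointwise 1-sigma interval, Delta = 3.841 to 95%.

A flat profile that never crosses the threshold marks a structurally or
practically non-identifiable parameter; the interval is reported as open
on that side (Table-style ">= bound" entries), not as an error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .estimation import FixedSubsetProblem, fit

__all__ = ["Profile", "ProfileCI", "profile_likelihood", "ci_and_sigma"]


@dataclass
class Profile:
    """Re-optimized -2 log L along a grid of fixed values of one parameter."""

    name: str
    values: np.ndarray      # grid of fixed values (estimation scale), sorted
    objective: np.ndarray   # re-optimized -2 log L at each grid value
    mle: float              # MLE of the parameter
    mle_objective: float
    delta: float            # threshold level above the optimum
    lower_open: bool = False  # profile never crossed on that side
    upper_open: bool = False
    thetas: list = field(default_factory=list)


@dataclass
class ProfileCI:
    name: str
    lower: float | None
    upper: float | None
    sigma: float | None
    sigma_is_lower_bound: bool = False
    delta: float = 1.0

    def format_fold(self, d_hat: float, invert: bool = False) -> str:
        """Table-style 'factor +/- sigma' (or '>= bound') on the fold scale."""
        fold = 10.0 ** (-d_hat if invert else d_hat)
        if self.sigma is None:
            return f"{fold:.3g} (unbounded)"
        if self.sigma_is_lower_bound:
            return f">= {10.0 ** self.sigma:.2g}"
        return f"{fold:.3g} +/- {fold * np.log(10) * self.sigma:.2g}"


def _reoptimize(problem, idx, value, warm_full):
    sub = FixedSubsetProblem(problem, {idx: float(value)})
    rec = fit(sub, sub.reduce(warm_full), max_iter=300)
    return float(rec.value), sub.expand(rec.theta)


def profile_likelihood(problem, theta_hat, name: str, delta: float = 1.0,
                       target_rise: float = 0.1, step_init: float = 0.02,
                       step_min: float = 1e-4, step_max: float = 0.5,
                       max_steps: int = 60) -> Profile:
    """Profile one coordinate of ``problem`` around the fit ``theta_hat``.

    ``delta`` is the stopping level above the optimum (the profile is
    traced until it exceeds MLE + delta on each side, a bound is hit, or
    the step budget is exhausted).  Deterministic given the fit.
    """
    names = problem.coord_names()
    idx = names.index(name)
    theta_hat = np.asarray(theta_hat, dtype=float)
    base = float(problem.neg2loglik(theta_hat))
    lb, ub = problem.bounds()
    points = [(float(theta_hat[idx]), base, theta_hat.copy())]
    open_side = {+1: True, -1: True}
    for direction in (+1, -1):
        x = float(theta_hat[idx])
        warm = theta_hat.copy()
        val_prev = base
        step = step_init
        for _ in range(max_steps):
            x_next = x + direction * step
            hit_bound = False
            if x_next <= lb[idx]:
                x_next, hit_bound = lb[idx], True
            elif x_next >= ub[idx]:
                x_next, hit_bound = ub[idx], True
            val, warm = _reoptimize(problem, idx, x_next, warm)
            points.append((x_next, val, warm.copy()))
            if val - base > delta:
                open_side[direction] = False
                break
            if hit_bound:
                break
            rise = max(val - val_prev, 1e-3)
            step = float(np.clip(step * np.clip(target_rise / rise, 0.5, 2.0),
                                 step_min, step_max))
            x, val_prev = x_next, val
    points.sort(key=lambda t: t[0])
    values = np.array([p[0] for p in points])
    objective = np.array([p[1] for p in points])
    return Profile(
        name=name, values=values, objective=objective,
        mle=float(theta_hat[idx]), mle_objective=base, delta=delta,
        lower_open=open_side[-1], upper_open=open_side[+1],
        thetas=[p[2] for p in points],
    )


def _crossing(xs, ys, level):
    """First monotone-interpolated crossing of ``level`` walking outward."""
    for (x0, y0), (x1, y1) in zip(zip(xs[:-1], ys[:-1]), zip(xs[1:], ys[1:])):
        if (y0 - level) * (y1 - level) <= 0 and y0 != y1:
            return x0 + (level - y0) * (x1 - x0) / (y1 - y0)
    return None


def ci_and_sigma(profile: Profile, delta: float | None = None) -> ProfileCI:
    """Interval limits at MLE + delta and the conservative sigma approximation.

    sigma is max(|mle - lower|, |upper - mle|) on the profiled (log10)
    scale.  If the profile is open on both sides sigma is undefined; open
    on one side, the finite side's distance is reported as a lower bound.
    """
    delta = profile.delta if delta is None else delta
    level = profile.mle_objective + delta
    i_mle = int(np.argmin(np.abs(profile.values - profile.mle)))
    left_x = profile.values[: i_mle + 1][::-1]
    left_y = profile.objective[: i_mle + 1][::-1]
    right_x = profile.values[i_mle:]
    right_y = profile.objective[i_mle:]
    lower = _crossing(left_x, left_y, level)
    upper = _crossing(right_x, right_y, level)
    if lower is None and upper is None:
        return ProfileCI(profile.name, None, None, None, delta=delta)
    if lower is None or upper is None:
        side = upper if lower is None else lower
        return ProfileCI(profile.name, lower, upper,
                         abs(side - profile.mle), sigma_is_lower_bound=True,
                         delta=delta)
    sigma = max(profile.mle - lower, upper - profile.mle)
    return ProfileCI(profile.name, float(lower), float(upper), float(sigma),
                     delta=delta)


def ci_level_delta(alpha: float = 0.05) -> float:
    """Threshold Delta for a (1-alpha) pointwise profile interval."""
    return float(chi2.ppf(1.0 - alpha, 1))
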