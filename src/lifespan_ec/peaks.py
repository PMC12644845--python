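"""Peak-age detection, growth-rate curves, and bootstrap peak CIs.

A peak is the largest interior local maximum of a fitted trajectory
(strictly larger than both neighbors; curve endpoints are excluded).
Inhibitory (negative) metrics are sign-flipped first, so their "peak"
is the age of strongest inhibition.  A curve with no interior local
maximum yields an explicit no-peak result, not an error.

Peak-age confidence intervals resample the age-smooth coefficient
posterior of the fitted growth model: each draw rebuilds the curve on
the age grid, the draw's peak age is recorded, and the CI is read from
the percentiles of that distribution.  Growth rate (velocity) is the
first derivative of the fitted curve by forward (Euler) differences
with respect to age in years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from lifespan_ec.trajectory import TrajectoryFit
from lifespan_ec.synth import inverse_transform_age


@dataclass
class PeakEstimate:
    """Point peak of a curve, with optional bootstrap CI attached."""

    found: bool
    peak_age: float = np.nan
    peak_value: float = np.nan
    sign: int = 1
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_draws: int = 0
    n_peakless_draws: int = 0
    max_rate_age: float = np.nan
    min_rate_age: float = np.nan


def find_peak(curve: np.ndarray, age_grid: np.ndarray, sign: int = 1) -> PeakEstimate:
    """Largest interior local maximum by the two-neighbor rule.

    ``sign=-1`` negates the curve first (inhibitory metrics).  The
    reported peak_value is on the original scale.
    """
    curve = np.asarray(curve, dtype=float)
    age_grid = np.asarray(age_grid, dtype=float)
    if len(curve) < 3:
        raise ValueError("need at least 3 grid points")
    work = sign * curve
    interior = np.arange(1, len(work) - 1)
    is_max = (work[interior] > work[interior - 1]) & (work[interior] > work[interior + 1])
    candidates = interior[is_max]
    if len(candidates) == 0:
        return PeakEstimate(found=False, sign=sign)
    best = candidates[np.argmax(work[candidates])]
    return PeakEstimate(
        found=True,
        peak_age=float(age_grid[best]),
        peak_value=float(curve[best]),
        sign=sign,
    )


def growth_rate(curve: np.ndarray, age_grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Velocity curve by forward differences with respect to age (years).

    Returns (velocity, midpoint_ages); length is one less than the grid.
    """
    curve = np.asarray(curve, dtype=float)
    age_grid = np.asarray(age_grid, dtype=float)
    d_age = np.diff(age_grid)
    if np.any(d_age <= 0):
        raise ValueError("age grid must be strictly increasing")
    velocity = np.diff(curve) / d_age
    return velocity, age_grid[:-1]


def rate_extremes(curve: np.ndarray, age_grid: np.ndarray) -> tuple[float, float]:
    """Ages of maximal increase and maximal decline of a curve."""
    velocity, ages = growth_rate(curve, age_grid)
    return float(ages[np.argmax(velocity)]), float(ages[np.argmin(velocity)])


def bootstrap_peak_ci(
    fit: TrajectoryFit,
    sign: int = 1,
    n_draws: int = 20_000,
    alpha: float = 0.05,
    seed: int = 0,
    grid_t: np.ndarray | None = None,
) -> PeakEstimate:
    """Bootstrap CI for the peak age from the coefficient posterior.

    Draws coefficient vectors from the multivariate normal posterior of
    the age-smooth coefficients, rebuilds the sex-0 curve per draw, and
    records each draw's peak age; draws with no interior maximum are
    dropped (their count is reported).  If more than half the draws are
    peakless the CI is reported missing.  Deterministic given ``seed``.
    """
    if n_draws < 100:
        raise ValueError("need at least 100 draws")
    if grid_t is None:
        grid_t = fit.default_grid()
    age_grid = inverse_transform_age(np.asarray(grid_t, dtype=float))
    point_curve = fit.predict(grid_t)["y_pred"].to_numpy()
    point = find_peak(point_curve, age_grid, sign=sign)
    point.max_rate_age, point.min_rate_age = rate_extremes(sign * point_curve, age_grid)

    rng = np.random.default_rng(seed)
    curves = fit.sample_age_curves(n_draws, rng, grid_t)
    work = sign * curves
    left = work[:, 1:-1] > work[:, :-2]
    right = work[:, 1:-1] > work[:, 2:]
    is_max = left & right
    has_peak = is_max.any(axis=1)
    n_peakless = int((~has_peak).sum())

    peak_ages = []
    masked = np.where(is_max, work[:, 1:-1], -np.inf)
    best_idx = masked.argmax(axis=1) + 1
    peak_ages = age_grid[best_idx][has_peak]

    point.n_draws = n_draws
    point.n_peakless_draws = n_peakless
    if n_peakless > n_draws / 2:
        return point  # CI left missing; diagnostic in n_peakless_draws
    lo, hi = np.percentile(peak_ages, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    point.ci_low, point.ci_high = float(lo), float(hi)
    return point
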