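"""Richards (generalized logistic) growth model for OD time series.

The model is

    y(x) = a * [1 + (d - 1) * exp(-k (x - xc))] ** (1 / (1 - d)),   d != 1

with upper asymptote ``a`` (OD units), rate constant ``k`` (1/day),
shape ``d`` (dimensionless, sigmoid branch d > 1) and inflection time
``xc`` (days).  At d = 2 it reduces to the ordinary logistic
a / (1 + exp(-k (x - xc))); at x = xc the value is a * d**(1/(1-d)).

The summary statistic fed to the downstream factorial statistics is the
average normalized growth rate

    rate = k / (2 (d + 1))      [1/day]

which is 0 by convention for wells called as no-growth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

DEFAULT_THRESHOLD_OD = 0.05   # absorbance; minimum max blank-subtracted OD
DEFAULT_THRESHOLD_R2 = 0.7    # minimum coefficient of determination


class RichardsDomainError(ValueError):
    """Raised when parameters leave the model's sigmoid branch (d > 1 etc.)."""


class InsufficientDataError(ValueError):
    """Raised when a series has too few points to fit."""


@dataclass(frozen=True)
class RichardsParams:
    """The four growth-curve parameters (a, k, d, xc)."""

    a: float    # upper asymptote, OD units
    k: float    # growth rate constant, 1/day
    d: float    # shape parameter, > 1
    xc: float   # inflection time, days

    def validate(self) -> None:
        if not (self.a > 0):
            raise RichardsDomainError(f"a must be > 0, got {self.a}")
        if not (self.k > 0):
            raise RichardsDomainError(f"k must be > 0, got {self.k}")
        if self.d == 1:
            raise RichardsDomainError("d = 1 is outside the model's domain")
        if not (self.d > 1):
            # the 0 < d < 1 decaying branch is rejected: growth curves here
            # are non-decreasing sigmoids
            raise RichardsDomainError(f"d must be > 1, got {self.d}")
        if not np.isfinite(self.xc):
            raise RichardsDomainError("xc must be finite")


@dataclass(frozen=True)
class FitResult:
    """Outcome of fitting one well's blank-subtracted series."""

    params: RichardsParams | None
    rate: float           # k / (2 (d + 1)); 0 when growth_flag is False
    rss: float
    r_squared: float
    converged: bool
    growth_flag: bool
    n_points: int


def evaluate_richards(params: RichardsParams, x) -> np.ndarray | float:
    """Evaluate the Richards curve at time(s) ``x`` (days)."""
    params.validate()
    x = np.asarray(x, dtype=float)
    z = 1.0 + (params.d - 1.0) * np.exp(-params.k * (x - params.xc))
    y = params.a * z ** (1.0 / (1.0 - params.d))
    return y if y.ndim else float(y)


def normalized_growth_rate(params: RichardsParams) -> float:
    """Average normalized growth rate k / (2 (d + 1)), in 1/day."""
    params.validate()
    return params.k / (2.0 * (params.d + 1.0))


def _initial_guess(t: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Heuristic start: a0 = max smoothed OD, xc0 = half-max crossing,
    k0 from the early quasi-exponential slope of log OD, d0 = 2."""
    if len(y) >= 5:
        smooth = np.convolve(y, np.ones(3) / 3.0, mode="same")
        smooth[0], smooth[-1] = y[0], y[-1]
    else:
        smooth = y
    a0 = max(float(np.max(smooth)), 1e-6)
    half = a0 / 2.0
    above = np.nonzero(smooth >= half)[0]
    xc0 = float(t[above[0]]) if len(above) else float(np.median(t))
    # slope of log OD over the window below half-max with positive signal
    mask = (smooth > max(0.05 * a0, 1e-6)) & (smooth < 0.8 * a0)
    if mask.sum() >= 2:
        slope = np.polyfit(t[mask], np.log(smooth[mask]), 1)[0]
        k0 = float(np.clip(slope, 0.05, 5.0))
    else:
        k0 = 0.5
    return np.array([a0, k0, 2.0, xc0])


def fit_richards(
    times,
    od,
    max_iter: int = 1000,
    xtol: float = 1e-12,
    threshold_od: float = DEFAULT_THRESHOLD_OD,
    threshold_r2: float = DEFAULT_THRESHOLD_R2,
) -> FitResult:
    """Least-squares fit of the Richards curve to one blank-subtracted series.

    Parameters are bounded to the sigmoid branch: a in (0, 2*max OD],
    k in (0, 10], d in (1, 20], xc in [min day - 5, max day + 5].
    Requires at least 5 time points.  The growth call combines a signal
    threshold on the maximum OD with a goodness-of-fit threshold on R²
    (see :func:`call_growth`).
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(od, dtype=float)
    if t.ndim != 1 or t.shape != y.shape:
        raise ValueError("times and od must be 1-d arrays of equal length")
    if len(t) < 5:
        raise InsufficientDataError(f"need >= 5 time points, got {len(t)}")
    if not np.all(np.isfinite(y)):
        raise ValueError("od contains non-finite values")

    y_max = float(np.max(y))
    tss = float(np.sum((y - y.mean()) ** 2))

    if y_max < threshold_od or tss == 0.0:
        # flat trace, or signal below the detection threshold: a growth
        # call is impossible by the threshold rule, so the solver is not
        # run and the series is recorded as no-growth
        return FitResult(None, 0.0, tss, 0.0, False, False, len(t))

    x0 = _initial_guess(t, y)
    lo = np.array([1e-9, 1e-9, 1.0 + 1e-9, float(t.min()) - 5.0])
    hi = np.array([2.0 * y_max, 10.0, 20.0, float(t.max()) + 5.0])
    x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)

    def residuals(p):
        a, k, d, xc = p
        z = 1.0 + (d - 1.0) * np.exp(-k * (t - xc))
        return a * z ** (1.0 / (1.0 - d)) - y

    sol = least_squares(
        residuals, x0, bounds=(lo, hi),
        xtol=xtol, ftol=1e-12, gtol=1e-12, max_nfev=max_iter,
    )
    params = RichardsParams(*map(float, sol.x))
    rss = float(np.sum(sol.fun ** 2))
    r2 = 1.0 - rss / tss
    converged = bool(sol.success)
    growth = call_growth(y, converged, r2, threshold_od, threshold_r2)
    rate = normalized_growth_rate(params) if growth else 0.0
    return FitResult(params, rate, rss, r2, converged, growth, len(t))


def call_growth(
    od,
    converged: bool,
    r_squared: float,
    threshold_od: float = DEFAULT_THRESHOLD_OD,
    threshold_r2: float = DEFAULT_THRESHOLD_R2,
) -> bool:
    """Deterministic growth/no-growth call for one well.

    True iff the maximum blank-subtracted OD is >= ``threshold_od`` AND
    the fit converged with R² >= ``threshold_r2`` (both boundaries
    inclusive).
    """
    od = np.asarray(od, dtype=float)
    return bool(
        float(np.max(od)) >= threshold_od
        and converged
        and r_squared >= threshold_r2
    )
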