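"""Activity level from detection times, by circular kernel density.

Camera traps only record animals while they are active, so the temporal
effort overstates availability for species with pronounced activity
schedules (nocturnal, crepuscular, partly cave-dwelling).  The standard
correction estimates the *activity level* A — the proportion of the day
the species is active — from independent detection times and divides
densities by A.

Clock times are mapped to the circle, a von Mises kernel density

    f(t) = (1/n) sum_i exp(kappa cos(t - t_i)) / (2 pi I0(kappa))

is fitted, and A = 1 / (2 pi max_t f(t)): under the model animals are
active for a fraction of the day proportional to mean/peak activity.
For a pure von Mises schedule with concentration kappa the closed form
is A = I0(kappa) exp(-kappa).  The kernel concentration is chosen by a
circular plug-in rule on the fitted von Mises concentration; the
confidence interval is a seeded nonparametric bootstrap over the event
times with the bandwidth held at its point-estimate value.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special

SECONDS_PER_DAY = 86400.0
_TWO_PI = 2.0 * np.pi
#: cap on the von Mises concentration (numerical guard for degenerate samples)
KAPPA_MAX = 500.0


class ActivityError(ValueError):
    pass


def to_circular(timestamps) -> np.ndarray:
    """Map clock times to radians in [0, 2 pi): seconds-since-midnight scaled.

    The date is discarded; only time of day matters for an activity cycle.
    """
    ts = pd.to_datetime(pd.Series(timestamps))
    secs = (
        ts.dt.hour * 3600 + ts.dt.minute * 60 + ts.dt.second + ts.dt.microsecond / 1e6
    )
    return (secs.to_numpy(dtype=float) / SECONDS_PER_DAY) * _TWO_PI


def _resultant_length(times: np.ndarray) -> float:
    return float(np.hypot(np.cos(times).mean(), np.sin(times).mean()))


def fit_kappa_mle(times: np.ndarray) -> float:
    """Von Mises concentration MLE via the A1-inverse approximation."""
    r = _resultant_length(np.asarray(times, dtype=float))
    if r < 1e-12:
        return 0.0
    if r < 0.53:
        kappa = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        denom = r**3 - 4 * r**2 + 3 * r  # -> 0 as r -> 1 (point mass)
        kappa = 1.0 / denom if denom > 1.0 / KAPPA_MAX else KAPPA_MAX
    return float(min(kappa, KAPPA_MAX))


def plugin_kappa(times: np.ndarray) -> float:
    """Plug-in kernel concentration from the fitted von Mises concentration.

    Circular analogue of a normal-reference bandwidth: with kappa-hat the
    MLE concentration and n the sample size,

        kappa* = (3 n kappa^2 I2(2 kappa) / (4 sqrt(pi) I1(kappa)^2))^(2/5).

    A nearly uniform sample gives kappa* ~ 0 (flat kernel, A -> 1).
    """
    times = np.asarray(times, dtype=float)
    n = times.size
    k = fit_kappa_mle(times)
    if k < 1e-8:
        return 1e-6
    # scaled Bessels: I2(2k)/I1(k)^2 = ive(2,2k)/i1e(k)^2 exactly (e^{2k} cancels)
    num = 3 * n * k**2 * special.ive(2, 2 * k)
    den = 4 * np.sqrt(np.pi) * special.i1e(k) ** 2
    return float(min((num / den) ** 0.4, KAPPA_MAX**2))


def vm_kde(times: np.ndarray, kappa: float):
    """Von Mises kernel density estimate; returns a vectorized callable.

    Computed in exponentially scaled form, so large concentrations do
    not overflow: f(t) = mean_i exp(kappa (cos(t - t_i) - 1)) / (2 pi I0e(kappa)).
    """
    if kappa <= 0:
        raise ActivityError(f"kernel concentration must be positive, got {kappa}")
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ActivityError("empty circular sample")
    denom = _TWO_PI * special.i0e(kappa)

    def f(t):
        t = np.atleast_1d(np.asarray(t, dtype=float))
        ker = np.exp(kappa * (np.cos(t[:, None] - times[None, :]) - 1.0))
        return ker.mean(axis=1) / denom

    return f


@dataclass
class ActivityEstimate:
    """Activity level A in (0, 1] with bootstrap CI and kernel bandwidth."""

    A: float
    ci: tuple[float, float]
    kappa: float
    n_events: int
    bootstrap: np.ndarray | None = None

    @property
    def cv(self) -> float:
        if self.bootstrap is None or len(self.bootstrap) < 2:
            return np.nan
        return float(np.std(self.bootstrap, ddof=1) / self.A)


def _peak_density(times, kappa, grid_size=512, refine=True):
    """max_t f(t) on a fixed grid, locally refined around the argmax."""
    f = vm_kde(times, kappa)
    grid = np.linspace(0.0, _TWO_PI, grid_size, endpoint=False)
    vals = f(grid)
    i = int(np.argmax(vals))
    peak = float(vals[i])
    if refine:
        h = _TWO_PI / grid_size
        res = optimize.minimize_scalar(
            lambda t: -f(t)[0], bounds=(grid[i] - h, grid[i] + h), method="bounded"
        )
        peak = max(peak, float(-res.fun))
    return peak


def activity_level(
    times,
    kappa: float | None = None,
    n_boot: int = 1000,
    grid_size: int = 512,
    ci_level: float = 0.95,
    rng=None,
) -> ActivityEstimate:
    """Estimate the activity level A from a circular sample of event times.

    A = 1 / (2 pi max f-hat), with the peak searched on a ``grid_size``
    grid and refined locally.  ``kappa`` overrides the plug-in
    bandwidth.  The bootstrap resamples event times with replacement
    (``n_boot`` replicates, percentile interval); set ``n_boot=0`` to
    skip it.
    """
    times = np.asarray(times, dtype=float)
    if np.any((times < 0) | (times >= _TWO_PI)):
        times = np.mod(times, _TWO_PI)
    n = times.size
    if n == 0:
        raise ActivityError("no event times")
    if n < 10:
        warnings.warn(f"only {n} independent events; A will be unstable", stacklevel=2)
    if kappa is None:
        kappa = plugin_kappa(times)
    kappa = max(float(kappa), 1e-6)

    peak = _peak_density(times, kappa, grid_size)
    a = float(min(1.0 / (_TWO_PI * peak), 1.0))
    if a <= 0.05:
        warnings.warn(
            "activity level at or below 0.05: sample is nearly degenerate",
            stacklevel=2,
        )

    boots = None
    ci = (a, a)
    if n_boot > 0:
        rng = np.random.default_rng(rng)
        grid = np.linspace(0.0, _TWO_PI, grid_size, endpoint=False)
        # kernel matrix once; a bootstrap replicate is a reweighting of columns
        ker = np.exp(kappa * (np.cos(grid[:, None] - times[None, :]) - 1.0))
        denom = _TWO_PI * special.i0e(kappa)
        weights = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot).T / n
        dens = (ker @ weights) / denom  # (grid, n_boot)
        peaks = dens.max(axis=0)
        boots = np.minimum(1.0 / (_TWO_PI * peaks), 1.0)
        alpha = 1.0 - ci_level
        lo, hi = np.quantile(boots, [alpha / 2, 1 - alpha / 2])
        ci = (float(min(lo, a)), float(max(hi, a)))
    return ActivityEstimate(A=a, ci=ci, kappa=float(kappa), n_events=n, bootstrap=boots)


def availability_correction(density_uncorrected: float, a: float) -> float:
    """Scale a density by 1/A: animals are only detectable while active."""
    if not (0.0 < a <= 1.0):
        raise ActivityError(f"activity level must be in (0, 1], got {a}")
    return density_uncorrected / a
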