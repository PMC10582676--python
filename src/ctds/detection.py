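"""Point-transect detection functions and their maximum-likelihood fit.

A detection function g(r) gives the probability that an animal present
at radial distance r from the camera at a snapshot moment is recorded.
Following standard distance-sampling practice it is a *key function*

    uniform      g(r) = 1
    half-normal  g(r) = exp(-r^2 / (2 sigma^2))
    hazard-rate  g(r) = 1 - exp(-(r / sigma)^{-b})

optionally multiplied by a series expansion ``1 + sum_j a_j s_j(r/w)``
with cosine, simple-polynomial or Hermite-polynomial terms.  The
evaluated g is clamped non-negative and rescaled so its maximum over the
truncation interval [l, w] is 1.

Distances are binned; the fit maximizes the multinomial likelihood of
the pooled bin counts with cell probabilities

    pi_j = int_{bin j} r g(r) dr / int_l^w r g(r) dr

(the radial weighting reflects point-transect geometry: the area of an
annulus at distance r grows like r).  The overall detection probability
within the surveyed annulus is

    P = int_l^w g(r) 2 r dr / (w^2 - l^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy import integrate, optimize, special, stats

from .io import BinnedCounts, BinningScheme

KEY_FAMILIES = ("uniform", "half-normal", "hazard-rate")
ADJUSTMENT_TYPES = ("none", "cosine", "simple-polynomial", "hermite-polynomial")

_GL_NODES, _GL_WEIGHTS = leggauss(24)


class ParameterError(ValueError):
    """A detection-function parameter is outside its valid domain."""


def eval_key(family: str, r, sigma: float | None = None, shape: float | None = None):
    """Evaluate the key function at distances ``r`` (vectorized).

    ``sigma`` is the scale in metres (half-normal and hazard-rate);
    ``shape`` is the hazard-rate shape b > 1.
    """
    r = np.asarray(r, dtype=float)
    if family == "uniform":
        return np.ones_like(r)
    if sigma is None or sigma <= 0:
        raise ParameterError(f"{family} key requires sigma > 0, got {sigma}")
    if family == "half-normal":
        return np.exp(-(r**2) / (2.0 * sigma**2))
    if family == "hazard-rate":
        if shape is None or shape <= 1:
            raise ParameterError(f"hazard-rate requires shape b > 1, got {shape}")
        with np.errstate(divide="ignore", over="ignore"):
            # (r/sigma)^(-b) -> inf as r -> 0, so g(0) = 1 exactly
            hazard = np.where(r > 0, np.power(r / sigma, -shape), np.inf)
            return -np.expm1(-hazard)
    raise ParameterError(f"unknown key family {family!r}")


def adjustment_terms(adjustment: str, orders, r_scaled) -> np.ndarray:
    """Series basis s_j evaluated at scaled distance r_s = r / w.

    cosine order j: cos(j pi r_s); simple polynomial: r_s^{2j};
    Hermite polynomial: He_{2j}(r_s) (probabilists' convention).
    Returns an array of shape (len(orders), len(r_scaled)).
    """
    rs = np.atleast_1d(np.asarray(r_scaled, dtype=float))
    orders = tuple(int(j) for j in orders)
    if adjustment == "none" or not orders:
        return np.zeros((0, rs.size))
    if adjustment == "cosine":
        return np.stack([np.cos(j * np.pi * rs) for j in orders])
    if adjustment == "simple-polynomial":
        return np.stack([rs ** (2 * j) for j in orders])
    if adjustment == "hermite-polynomial":
        return np.stack([special.eval_hermitenorm(2 * j, rs) for j in orders])
    raise ParameterError(f"unknown adjustment type {adjustment!r}")


def n_free_parameters(family: str, orders) -> int:
    base = {"uniform": 0, "half-normal": 1, "hazard-rate": 2}[family]
    return base + len(tuple(orders))


@dataclass
class DetectionModel:
    """A key + adjustment detection function tied to a binning scheme.

    Parameter fields are in natural units (sigma in metres).  ``vcov``
    is the inverse observed information in the optimizer's internal
    coordinates (log sigma, log(b-1), raw adjustment coefficients);
    ``wald_ci`` maps it back to natural scale.
    """

    key_family: str
    binning: BinningScheme
    adjustment: str = "none"
    orders: tuple[int, ...] = ()
    sigma: float | None = None
    shape: float | None = None
    coefficients: tuple[float, ...] = ()
    loglik: float = np.nan
    converged: bool = False
    vcov: np.ndarray | None = None
    message: str = ""

    def __post_init__(self):
        if self.key_family not in KEY_FAMILIES:
            raise ParameterError(f"unknown key family {self.key_family!r}")
        if self.adjustment not in ADJUSTMENT_TYPES:
            raise ParameterError(f"unknown adjustment {self.adjustment!r}")
        self.orders = tuple(int(j) for j in self.orders)
        if len(set(self.orders)) != len(self.orders):
            raise ParameterError("adjustment orders must be distinct")
        self.coefficients = tuple(float(a) for a in self.coefficients)
        if self.adjustment != "none" and len(self.coefficients) not in (
            0,
            len(self.orders),
        ):
            raise ParameterError("one coefficient per adjustment order required")

    # ------------------------------------------------------------------
    @property
    def n_params(self) -> int:
        """Free parameters K: key parameters + adjustment coefficients."""
        return n_free_parameters(self.key_family, self.orders)

    def _g_unscaled(self, r) -> np.ndarray:
        """key * (1 + series), clamped at 0; not yet rescaled to max 1."""
        r = np.atleast_1d(np.asarray(r, dtype=float))
        g = eval_key(self.key_family, r, self.sigma, self.shape)
        if self.adjustment != "none" and self.coefficients:
            terms = adjustment_terms(self.adjustment, self.orders, r / self.binning.w)
            g = g * (1.0 + np.asarray(self.coefficients) @ terms)
        return np.clip(g, 0.0, None)

    def rescale_factor(self) -> float:
        """max of the unscaled g over [l, w] (grid search + local refine)."""
        l, w = self.binning.left_truncation, self.binning.w
        grid = np.linspace(l, w, 513)
        vals = self._g_unscaled(grid)
        i = int(np.argmax(vals))
        lo = grid[max(i - 1, 0)]
        hi = grid[min(i + 1, grid.size - 1)]
        res = optimize.minimize_scalar(
            lambda r: -self._g_unscaled(r)[0], bounds=(lo, hi), method="bounded"
        )
        peak = max(vals[i], -res.fun)
        if peak <= 0:
            raise ParameterError("detection function vanishes on [l, w]")
        return float(peak)

    def g(self, r) -> np.ndarray:
        """The detection function, rescaled so max over [l, w] is 1."""
        return self._g_unscaled(r) / self.rescale_factor()

    # ------------------------------------------------------------------
    def detection_probability(self) -> float:
        """P = int_l^w g(r) 2 r dr / (w^2 - l^2), by adaptive quadrature."""
        l, w = self.binning.left_truncation, self.binning.w
        if self.key_family == "uniform" and (
            self.adjustment == "none" or not self.coefficients
        ):
            return 1.0
        scale = self.rescale_factor()
        val, _ = integrate.quad(
            lambda r: self._g_unscaled(r)[0] / scale * 2.0 * r,
            l,
            w,
            limit=200,
        )
        p = val / (w**2 - l**2)
        if not np.isfinite(p):
            raise FloatingPointError("non-finite detection probability integrand")
        return float(min(p, 1.0))

    def _bin_integrals(self) -> np.ndarray:
        """int_{bin j} r g(r) dr per bin via fixed Gauss-Legendre rule."""
        cp = np.asarray(self.binning.cutpoints)
        a, b = cp[:-1], cp[1:]
        half = 0.5 * (b - a)
        mid = 0.5 * (a + b)
        # nodes: (n_bins, n_nodes)
        r = mid[:, None] + half[:, None] * _GL_NODES[None, :]
        vals = (self._g_unscaled(r.ravel()) * r.ravel()).reshape(r.shape)
        return half * (vals @ _GL_WEIGHTS)

    def bin_probabilities(self) -> np.ndarray:
        """Multinomial cell probabilities pi_j over the distance bins."""
        if self.binning.n_bins < 2:
            raise ParameterError("bin probabilities need at least 2 bins")
        integ = self._bin_integrals()
        total = integ.sum()
        if total <= 0 or not np.isfinite(total):
            raise FloatingPointError("degenerate detection function: zero mass")
        return integ / total

    def loglikelihood(self, binned_counts) -> float:
        """Multinomial log-likelihood of pooled bin counts under this model."""
        m = _pooled(binned_counts)
        pi = self.bin_probabilities()
        occupied = m > 0
        if np.any(occupied & (pi <= 0)):
            return -np.inf
        return float(np.sum(m[occupied] * np.log(pi[occupied])))

    def with_internal(self, x: np.ndarray) -> "DetectionModel":
        """Copy of this model with parameters set from internal coordinates."""
        sigma, shape, coefs = _unpack(self.key_family, len(self.orders), x)
        return replace(self, sigma=sigma, shape=shape, coefficients=coefs)

    @property
    def internal(self) -> np.ndarray:
        return _pack(self.key_family, self.sigma, self.shape, self.coefficients)


def _pooled(binned_counts) -> np.ndarray:
    if isinstance(binned_counts, BinnedCounts):
        return binned_counts.pooled
    return np.asarray(binned_counts, dtype=float)


# ----------------------------------------------------------------------
# internal parameterization: unconstrained optimizer coordinates
def _pack(family, sigma, shape, coefs) -> np.ndarray:
    x = []
    if family in ("half-normal", "hazard-rate"):
        x.append(np.log(sigma))
    if family == "hazard-rate":
        x.append(np.log(shape - 1.0))
    x.extend(coefs)
    return np.asarray(x, dtype=float)


def _unpack(family, n_coefs, x):
    x = np.asarray(x, dtype=float)
    i = 0
    sigma = shape = None
    if family in ("half-normal", "hazard-rate"):
        sigma = float(np.exp(np.clip(x[i], -20, 20)))
        i += 1
    if family == "hazard-rate":
        shape = 1.0 + float(np.exp(np.clip(x[i], -20, 20)))
        i += 1
    coefs = tuple(float(c) for c in x[i : i + n_coefs])
    return sigma, shape, coefs


def _mean_binned_distance(pooled: np.ndarray, scheme: BinningScheme) -> float:
    cp = np.asarray(scheme.cutpoints)
    mids = 0.5 * (cp[:-1] + cp[1:])
    n = pooled.sum()
    return float((pooled @ mids) / n) if n > 0 else 0.5 * scheme.w


def fit_mle(
    key_family: str,
    adjustment: str,
    orders,
    binned_counts: BinnedCounts,
    binning: BinningScheme | None = None,
    n_restarts: int = 5,
    rng=None,
) -> DetectionModel:
    """Fit a key + adjustment detection function to binned counts by ML.

    The optimizer works in unconstrained coordinates (log sigma,
    log(b-1), raw coefficients) with a multi-start quasi-Newton search:
    sigma starts at the mean retained distance, b at 2.5, coefficients
    at 0, followed by ``n_restarts`` jittered restarts.  Non-convergence
    is flagged on the returned model rather than raised, so a model grid
    can proceed ("excluding the models that did not converge" happens at
    selection time).  The covariance of the internal parameters comes
    from the numerically differentiated observed information.
    """
    if binning is None:
        binning = binned_counts.scheme
    rng = np.random.default_rng(rng)
    orders = tuple(int(j) for j in orders)
    pooled = _pooled(binned_counts)
    k = n_free_parameters(key_family, orders)
    n = pooled.sum()

    template = DetectionModel(
        key_family=key_family,
        binning=binning,
        adjustment=adjustment if orders else "none",
        orders=orders,
        coefficients=(0.0,) * len(orders),
        sigma=1.0 if key_family != "uniform" else None,
        shape=2.5 if key_family == "hazard-rate" else None,
    )

    n_nonzero = int(np.sum(pooled > 0))
    if n_nonzero < 2 or n_nonzero <= k:
        return replace(
            template,
            converged=False,
            message=f"degenerate data: {n_nonzero} non-empty bin(s) for {k} parameter(s)",
        )
    if n < 10 * max(k, 1):
        warnings.warn(
            f"only {int(n)} pooled observations for {k} parameters "
            f"({key_family}/{adjustment}); fit may be unstable",
            stacklevel=2,
        )

    if k == 0:
        ll = template.loglikelihood(pooled)
        return replace(
            template, loglik=ll, converged=True, vcov=np.zeros((0, 0))
        )

    def nll(x):
        model = template.with_internal(x)
        try:
            ll = model.loglikelihood(pooled)
        except FloatingPointError:
            return 1e10
        return -ll if np.isfinite(ll) else 1e10

    mean_d = max(_mean_binned_distance(pooled, binning), 1e-3)
    x0 = _pack(
        key_family,
        mean_d if key_family != "uniform" else None,
        2.5 if key_family == "hazard-rate" else None,
        (0.0,) * len(orders),
    )

    best = None
    starts = [x0]
    for _ in range(n_restarts):
        jitter = rng.normal(scale=0.4, size=x0.size)
        starts.append(x0 + jitter)
    for start in starts:
        res = optimize.minimize(nll, start, method="L-BFGS-B")
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success and best.fun < 1e9:
            break

    ok = best is not None and best.fun < 1e9 and np.isfinite(best.fun)
    model = template.with_internal(best.x if best is not None else x0)
    model = replace(
        model,
        loglik=-best.fun if ok else np.nan,
        converged=bool(ok),
        message="" if ok else f"optimizer failed: {getattr(best, 'message', '')}",
    )
    if ok:
        model.vcov = _vcov_from_hessian(nll, best.x)
    return model


def _vcov_from_hessian(nll, x, h: float = 1e-4) -> np.ndarray | None:
    """Inverse observed information by central finite differences."""
    p = x.size
    H = np.empty((p, p))
    f0 = nll(x)
    steps = h * np.maximum(1.0, np.abs(x))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p)
            ej = np.zeros(p)
            ei[i] = steps[i]
            ej[j] = steps[j]
            if i == j:
                H[i, i] = (nll(x + ei) - 2 * f0 + nll(x - ei)) / steps[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    nll(x + ei + ej)
                    - nll(x + ei - ej)
                    - nll(x - ei + ej)
                    + nll(x - ei - ej)
                ) / (4 * steps[i] * steps[j])
    try:
        return np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return np.linalg.pinv(H)


def wald_ci(model: DetectionModel, parameter: str = "sigma", level: float = 0.95):
    """Wald confidence interval for a natural-scale key parameter.

    The interval is built on the internal (log) scale where the sampling
    distribution is closer to normal, then exponentiated.
    """
    if model.vcov is None or model.vcov.size == 0:
        raise ParameterError("model has no covariance (not fitted or 0 parameters)")
    z = stats.norm.ppf(0.5 * (1 + level))
    if parameter == "sigma":
        idx = 0
        center = np.log(model.sigma)
        back = np.exp
    elif parameter == "shape":
        if model.key_family != "hazard-rate":
            raise ParameterError("shape only exists for the hazard-rate key")
        idx = 1
        center = np.log(model.shape - 1.0)
        back = lambda v: 1.0 + np.exp(v)
    else:
        raise ParameterError(f"unknown parameter {parameter!r}")
    se = float(np.sqrt(max(model.vcov[idx, idx], 0.0)))
    return back(center - z * se), back(center + z * se)
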