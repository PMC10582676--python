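"""The camera-trap point-transect density estimator with uncertainty.

For cameras k = 1..K with snapshot effort e_k = (theta/2pi) T_k / t and
n_k retained distance observations within the surveyed annulus
[l, w], the group density is

    D = sum_k n_k / (pi (w^2 - l^2) sum_k e_k P-hat) * 1/A

with P-hat the detection probability within the annulus from the
selected detection function and A the activity level (availability
correction).  Animal density multiplies by the mean group size.

Uncertainty combines three delta-method components on the CV scale:
the effort-weighted between-camera variance of the encounter rate
n_k / e_k, the detection-probability variance propagated from the
fit's parameter covariance, and the activity bootstrap variance.  The
95% interval is lognormal: D * exp(+/- z sqrt(ln(1 + cv^2))).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .activity import ActivityEstimate, availability_correction
from .detection import DetectionModel
from .io import BinnedCounts

#: m^2 per km^2 — densities are computed per m^2 and reported per km^2
M2_PER_KM2 = 1.0e6


class DensityError(ValueError):
    pass


def snapshot_effort(deployments: pd.DataFrame, t: float) -> pd.Series:
    """Snapshot effort e_k = (theta / 2 pi) * (T_k / t) per camera.

    ``deployments`` must carry ``theta_fov`` (radians) and ``T_k``
    (seconds) as produced by :func:`ctds.io.read_deployments`; ``t`` is
    the snapshot interval in seconds.
    """
    if t <= 0:
        raise DensityError(f"snapshot interval must be positive, got {t}")
    theta = deployments["theta_fov"].astype(float)
    if ((theta <= 0) | (theta > 2 * np.pi)).any():
        raise DensityError("theta_fov must lie in (0, 2 pi]")
    e = (theta / (2 * np.pi)) * (deployments["T_k"].astype(float) / t)
    e.name = "e_k"
    return e


@dataclass
class DensityEstimate:
    """Density in individuals per km^2 with CV and lognormal 95% CI."""

    density: float
    stratum: str = "overall"
    cv: float = np.nan
    ci: tuple[float, float] = (np.nan, np.nan)
    components: dict = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


def estimate_density(
    n_by_camera: pd.Series,
    e_by_camera: pd.Series,
    p_hat: float,
    w: float,
    left: float = 0.0,
    activity: float | ActivityEstimate | None = 1.0,
    mean_group_size: float = 1.0,
    stratum: str = "overall",
) -> DensityEstimate:
    """Point estimate of animal density (individuals / km^2).

    ``n_by_camera`` and ``e_by_camera`` are aligned on camera id; ``w``
    and ``left`` are the truncation distances in metres.  ``activity``
    may be an :class:`ActivityEstimate`, a float A, or None (uncorrected,
    flagged).
    """
    e = e_by_camera.astype(float)
    n = n_by_camera.reindex(e.index).fillna(0.0).astype(float)
    total_e = float(e.sum())
    if total_e <= 0:
        raise DensityError("total snapshot effort is zero")
    if not (0.0 < p_hat <= 1.0):
        raise DensityError(f"detection probability must be in (0, 1], got {p_hat}")
    if w <= left:
        raise DensityError("right truncation must exceed left truncation")

    annulus = np.pi * (w**2 - left**2)
    flags = []
    d_group_m2 = float(n.sum()) / (annulus * total_e * p_hat)
    d_group = d_group_m2 * M2_PER_KM2

    if activity is None:
        a = 1.0
        flags.append("no activity estimate: density is availability-uncorrected")
    else:
        a = activity.A if isinstance(activity, ActivityEstimate) else float(activity)
    d = availability_correction(d_group, a) * mean_group_size
    if n.sum() == 0:
        flags.append("zero detections in stratum")
    return DensityEstimate(
        density=d,
        stratum=stratum,
        components={
            "n_total": float(n.sum()),
            "effort_total": total_e,
            "p_hat": float(p_hat),
            "activity_level": a,
            "mean_group_size": float(mean_group_size),
            "n_cameras": int(len(e)),
            "w": float(w),
            "left": float(left),
        },
        flags=flags,
    )


def encounter_rate_cv(n_by_camera: pd.Series, e_by_camera: pd.Series) -> float:
    """CV of the pooled encounter rate from between-camera variability.

    Effort-weighted between-point estimator (the point-transect
    analogue of the standard between-line variance):

        var(n/E) = K / (E^2 (K-1)) * sum_k e_k^2 (n_k/e_k - n/E)^2
    """
    e = e_by_camera.astype(float)
    e = e[e > 0]
    n = n_by_camera.reindex(e.index).fillna(0.0).astype(float)
    k = len(e)
    if k < 2:
        raise DensityError("encounter-rate variance needs >= 2 cameras with effort")
    total_e, total_n = e.sum(), n.sum()
    if total_n == 0:
        return np.nan
    rate = total_n / total_e
    var = k / (total_e**2 * (k - 1)) * float((e**2 * (n / e - rate) ** 2).sum())
    return float(np.sqrt(var) / rate)


def detection_probability_cv(model: DetectionModel, step: float = 1e-4) -> float:
    """Delta-method CV of P-hat through the fit's parameter covariance."""
    if model.vcov is None:
        raise DensityError("model has no parameter covariance")
    if model.vcov.size == 0:
        return 0.0  # no free parameters (uniform null): P-hat is exact
    x = model.internal
    grad = np.empty_like(x)
    for i in range(x.size):
        h = step * max(1.0, abs(x[i]))
        xp, xm = x.copy(), x.copy()
        xp[i] += h
        xm[i] -= h
        grad[i] = (
            model.with_internal(xp).detection_probability()
            - model.with_internal(xm).detection_probability()
        ) / (2 * h)
    var = float(grad @ model.vcov @ grad)
    p = model.detection_probability()
    return float(np.sqrt(max(var, 0.0)) / p)


def lognormal_ci(d: float, cv: float, z: float = 1.959963984540054):
    """Lognormal CI: (D / C, D * C), C = exp(z sqrt(ln(1 + cv^2)))."""
    if d == 0 or not np.isfinite(cv):
        return (0.0, np.nan)
    c = np.exp(z * np.sqrt(np.log1p(cv**2)))
    return (d / c, d * c)


def variance_and_ci(
    estimate: DensityEstimate,
    n_by_camera: pd.Series,
    e_by_camera: pd.Series,
    model: DetectionModel | None = None,
    activity: ActivityEstimate | None = None,
) -> DensityEstimate:
    """Attach CV and 95% lognormal CI to a density estimate.

    The squared CV is the sum of the encounter-rate, detection and
    activity components (delta method on independent factors).
    """
    comps = {}
    try:
        comps["cv_encounter"] = encounter_rate_cv(n_by_camera, e_by_camera)
    except DensityError:
        comps["cv_encounter"] = np.nan
        estimate.flags.append("single camera: encounter-rate variance undefined")
    if model is not None:
        comps["cv_detection"] = detection_probability_cv(model)
    else:
        comps["cv_detection"] = 0.0
    if activity is not None and activity.bootstrap is not None:
        comps["cv_activity"] = activity.cv
    else:
        comps["cv_activity"] = 0.0

    cv2 = sum(c**2 for c in comps.values() if np.isfinite(c))
    estimate.cv = float(np.sqrt(cv2))
    estimate.ci = lognormal_ci(estimate.density, estimate.cv)
    estimate.components.update(comps)
    if estimate.density == 0:
        estimate.flags.append("zero density: one-sided interval")
    return estimate


def stratified_densities(
    binned: BinnedCounts,
    deployments: pd.DataFrame,
    efforts: pd.Series,
    model: DetectionModel,
    activity: ActivityEstimate | None = None,
    mean_group_size: float = 1.0,
) -> list[DensityEstimate]:
    """Densities per stratum plus overall, sharing one pooled fit and A.

    The detection function and activity level are estimated on pooled
    data (robustness by pooling); only counts and effort are stratified.
    ``deployments`` supplies the ``stratum`` label per camera.
    """
    p_hat = model.detection_probability()
    w = model.binning.w
    left = model.binning.left_truncation
    n_k = binned.n_by_camera.reindex(efforts.index).fillna(0).astype(float)

    out = []
    overall = estimate_density(
        n_k, efforts, p_hat, w, left, activity, mean_group_size, stratum="overall"
    )
    out.append(variance_and_ci(overall, n_k, efforts, model, activity))
    for stratum, dep in deployments.groupby("stratum"):
        cams = dep.index
        est = estimate_density(
            n_k.loc[cams],
            efforts.loc[cams],
            p_hat,
            w,
            left,
            activity,
            mean_group_size,
            stratum=str(stratum),
        )
        out.append(variance_and_ci(est, n_k.loc[cams], efforts.loc[cams], model, activity))
    return out
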