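"""Reference-region graphical (Patlak-Gjedde) estimation of the influx slope.

The transform maps an irreversible-uptake tissue curve and a reference curve
into coordinates where the late part of the data is a line whose slope is the
influx constant ``ki_cer`` (1/min):

    x(t) = int_0^t C_R dtau / C_R(t)      ("normalised time", min)
    y(t) = C_T(t) / C_R(t)

Frames are represented by their midpoints and the running integral uses the
trapezoid rule anchored at ``C_R(0) = 0``; the synthetic generator uses the
identical rule, so noiseless synthetic data are recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .core import MaskVolume, ReferenceTAC, SubjectScan, TissueTAC

__all__ = [
    "PatlakPoints",
    "PatlakFit",
    "ParametricMap",
    "reference_integral_min",
    "patlak_transform",
    "fit_patlak",
    "roi_ki",
    "parametric_map",
]

DEFAULT_T_STAR_MIN = 30.0


def reference_integral_min(ref: ReferenceTAC) -> np.ndarray:
    """Running trapezoid integral of the reference curve at frame midpoints.

    Anchored at (t=0, C=0); units kBq/mL * min. This is the shared
    discretisation contract between the simulator and the estimator.
    """
    t = np.concatenate(([0.0], ref.schedule.mid_min))
    c = np.concatenate(([0.0], ref.activity))
    steps = 0.5 * (c[1:] + c[:-1]) * np.diff(t)
    return np.cumsum(steps)


@dataclass(frozen=True)
class PatlakPoints:
    """Graphical-analysis coordinates, one point per frame midpoint."""

    x: np.ndarray  # normalised time, min
    y: np.ndarray  # tissue/reference activity ratio
    t_min: np.ndarray  # frame midpoints, min
    frame_durations_min: np.ndarray


@dataclass(frozen=True)
class PatlakFit:
    ki_cer: float  # influx slope, 1/min
    intercept: float
    t_star: float  # first fitted time, min
    n_points_used: int
    r_squared: float
    residual_sd: float
    weights: str = "uniform"


@dataclass(frozen=True)
class ParametricMap:
    """Voxel-wise influx-slope and intercept volumes (background = 0)."""

    ki: np.ndarray
    intercept: np.ndarray
    t_star: float
    n_failed: int


def patlak_transform(tissue: TissueTAC, ref: ReferenceTAC) -> PatlakPoints:
    """Map a tissue/reference curve pair into graphical-analysis coordinates."""
    if tissue.schedule.n_frames != ref.schedule.n_frames:
        raise ValueError(
            f"tissue has {tissue.schedule.n_frames} frames but reference has "
            f"{ref.schedule.n_frames}"
        )
    cr = ref.activity
    bad = np.flatnonzero(cr[1:] <= 0) + 1
    if bad.size:
        raise ValueError(f"non-positive reference activity at frame {bad[0]}")
    x = reference_integral_min(ref)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(cr > 0, x / cr, np.nan)
        y = np.where(cr > 0, tissue.activity / cr, np.nan)
    return PatlakPoints(x, y, ref.schedule.mid_min, ref.schedule.durations_min)


def _wls_line(x: np.ndarray, y: np.ndarray, w: np.ndarray):
    sw = np.sqrt(w)
    design = np.column_stack((x * sw, sw))
    coef, *_ = np.linalg.lstsq(design, y * sw, rcond=None)
    slope, intercept = float(coef[0]), float(coef[1])
    resid = y - (slope * x + intercept)
    ss_res = float(np.sum(w * resid**2))
    ybar = float(np.average(y, weights=w))
    ss_tot = float(np.sum(w * (y - ybar) ** 2))
    r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
    dof = x.size - 2
    resid_sd = float(np.sqrt(ss_res / dof)) if dof > 0 else 0.0
    return slope, intercept, min(r2, 1.0), resid_sd


def fit_patlak(
    points: PatlakPoints,
    t_star: float = DEFAULT_T_STAR_MIN,
    weights: str = "uniform",
) -> PatlakFit:
    """Least-squares line through the points at ``t >= t_star`` (minutes).

    ``weights`` is ``"uniform"`` or ``"duration"`` (frame-duration weighted).
    """
    if weights not in ("uniform", "duration"):
        raise ValueError("weights must be 'uniform' or 'duration'")
    sel = (points.t_min >= t_star) & np.isfinite(points.x) & np.isfinite(points.y)
    n = int(sel.sum())
    if n < 3:
        raise ValueError(f"need >=3 usable points at t >= {t_star} min, found {n}")
    x, y = points.x[sel], points.y[sel]
    w = points.frame_durations_min[sel] if weights == "duration" else np.ones(n)
    slope, intercept, r2, resid_sd = _wls_line(x, y, w)
    return PatlakFit(slope, intercept, float(t_star), n, r2, resid_sd, weights)


def roi_ki(
    scan: SubjectScan,
    region: int | str,
    t_star: float = DEFAULT_T_STAR_MIN,
    weights: str = "uniform",
) -> PatlakFit:
    """Influx slope of a region: average the region voxels, then fit."""
    tissue = scan.region_tac(region)
    ref = scan.reference_tac()
    return fit_patlak(patlak_transform(tissue, ref), t_star, weights)


def parametric_map(
    scan: SubjectScan,
    t_star: float = DEFAULT_T_STAR_MIN,
    weights: str = "uniform",
    smooth_fwhm_mm: float = 0.0,
) -> ParametricMap:
    """Independent per-voxel line fit over striatal and extra-striatal labels.

    Optional isotropic Gaussian pre-smoothing (FWHM in mm, off by default).
    Voxels whose transformed coordinates are not finite are set to NaN and
    counted in ``n_failed``.
    """
    mask = scan.mask
    data = scan.data
    if smooth_fwhm_mm > 0:
        sigma_vox = smooth_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / mask.voxel_size_mm
        data = np.stack(
            [ndimage.gaussian_filter(data[..., f], sigma_vox) for f in range(data.shape[-1])],
            axis=-1,
        )
    ref = scan.reference_tac()
    cr = ref.activity
    if np.any(cr[1:] <= 0):
        raise ValueError("non-positive reference activity; cannot map")
    xint = reference_integral_min(ref)
    t_mid = scan.schedule.mid_min
    with np.errstate(divide="ignore", invalid="ignore"):
        x = np.where(cr > 0, xint / cr, np.nan)
    sel = (t_mid >= t_star) & np.isfinite(x)
    if int(sel.sum()) < 3:
        raise ValueError(f"need >=3 frames at t >= {t_star} min")
    w = scan.schedule.durations_min[sel] if weights == "duration" else np.ones(int(sel.sum()))

    idx = np.concatenate(
        [mask.region_indices("striatum"), mask.region_indices("extra_striatal")]
    )
    flat = data.reshape(-1, scan.schedule.n_frames)
    with np.errstate(divide="ignore", invalid="ignore"):
        y = flat[idx][:, sel] / cr[sel]  # (V, F_sel)

    sw = np.sqrt(w)
    design = np.column_stack((x[sel] * sw, sw))
    ok = np.all(np.isfinite(y), axis=1)
    coef = np.full((2, idx.size), np.nan)
    if ok.any():
        sol, *_ = np.linalg.lstsq(design, (y[ok] * sw).T, rcond=None)
        coef[:, ok] = sol

    ki_vol = np.zeros(mask.data.size)
    ic_vol = np.zeros(mask.data.size)
    ki_vol[idx] = coef[0]
    ic_vol[idx] = coef[1]
    return ParametricMap(
        ki=ki_vol.reshape(mask.data.shape),
        intercept=ic_vol.reshape(mask.data.shape),
        t_star=float(t_star),
        n_failed=int((~ok).sum()),
    )
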