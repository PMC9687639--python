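"""Rotational-projection sac isolation.

The algorithm delimits the dilated sac of an abdominal aortic aneurysm from
its non-dilated necks using only the wall surface geometry:

1. centre the surface at the origin and rotate it about the craniocaudal
   (Z) axis in fixed angular increments, 360/theta_z projections in total;
2. for each rotation, drop the depth coordinate and extract the 2D
   silhouette of the node cloud in the (x, z) plane, split at x = 0 into a
   left and a right boundary curve;
3. fit each boundary curve with a trigonometric Fourier series (default
   seven harmonics) whose fundamental frequency is itself a fitted
   parameter;
4. locate the sac limits at the curvature-change flanks of the fitted
   series — the local extrema of its second derivative that bracket the
   point of maximum bulge;
5. aggregate the per-projection limits by their median and emit the node
   mask of all nodes between the inferior and superior bound.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, MeshValidationError, NoSacDetectedError, SacIsolationError
from .mesh_core import SurfaceMesh, center_at_origin

__all__ = [
    "RotationConfig",
    "ProjectionCurve",
    "FourierFit",
    "SacBounds",
    "SacRegion",
    "rotate_about_z",
    "project_silhouette",
    "fit_fourier",
    "fit_fourier_sweep",
    "fourier_eval",
    "fourier_derivatives",
    "detect_sac_bounds",
    "isolate_sac",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RotationConfig:
    """Angular increment theta_z (degrees) for the full 360-degree sweep.

    The increment must divide 360 evenly and yield at least 4 projections,
    i.e. theta_z in (0, 90].
    """

    increment_deg: float = 7.5

    def __post_init__(self):
        inc = float(self.increment_deg)
        if not (0.0 < inc <= 90.0):
            raise MeshValidationError("increment_deg must lie in (0, 90]")
        ratio = 360.0 / inc
        if abs(ratio - round(ratio)) > 1e-9:
            raise MeshValidationError(
                f"360 / increment_deg must be an integer (got {ratio!r})"
            )
        if round(ratio) < 4:
            raise MeshValidationError("at least 4 projections are required")

    @property
    def n_projections(self) -> int:
        return int(round(360.0 / self.increment_deg))

    def angles(self) -> np.ndarray:
        """Rotation angles in degrees: 0, theta_z, ..., 360 - theta_z."""
        return np.arange(self.n_projections) * float(self.increment_deg)


@dataclass
class ProjectionCurve:
    """One silhouette branch: projected extreme x (mm) versus z (mm)."""

    rotation_deg: float
    side: str  # "left" | "right"
    z: np.ndarray
    x: np.ndarray

    def __post_init__(self):
        self.z = np.asarray(self.z, dtype=np.float64)
        self.x = np.asarray(self.x, dtype=np.float64)
        if self.side not in ("left", "right"):
            raise MeshValidationError("side must be 'left' or 'right'")
        if self.z.shape != self.x.shape or self.z.ndim != 1:
            raise MeshValidationError("curve samples must be matching 1D arrays")
        if np.any(np.diff(self.z) <= 0):
            raise MeshValidationError("curve z samples must be strictly increasing")
        tol = 1e-9
        if self.side == "right" and np.any(self.x < -tol):
            raise MeshValidationError(
                "right-branch silhouette crosses the dividing axis (x < 0); "
                "is the mesh centred?"
            )
        if self.side == "left" and np.any(self.x > tol):
            raise MeshValidationError(
                "left-branch silhouette crosses the dividing axis (x > 0); "
                "is the mesh centred?"
            )

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class FourierFit:
    """Fitted series x(z) = a0 + sum_i a_i cos(i w z) + b_i sin(i w z)."""

    a0: float
    a: np.ndarray
    b: np.ndarray
    w: float
    n: int
    rmse: float

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        if not (1 <= int(self.n) <= 8):
            raise MeshValidationError("harmonic count n must lie in [1, 8]")
        if len(self.a) != self.n or len(self.b) != self.n:
            raise MeshValidationError("coefficient arrays must have length n")
        if not np.isfinite(self.rmse) or self.rmse < 0:
            raise MeshValidationError("rmse must be finite and non-negative")


@dataclass
class SacBounds:
    """Per-curve inferior/superior sac limits with fallback flags.

    A fallback flag marks a side where no second-derivative extremum existed
    and the corresponding end of the z-range was used instead; such bounds
    are excluded from the cross-projection aggregation.
    """

    z_inf: float
    z_sup: float
    fallback_inf: bool = False
    fallback_sup: bool = False


@dataclass
class SacRegion:
    """Aggregated sac: z bounds (centred frame), node mask, per-projection detail."""

    z_inferior: float
    z_superior: float
    node_mask: np.ndarray
    per_projection_bounds: list = field(default_factory=list)
    offset_applied: np.ndarray | None = None

    def __post_init__(self):
        self.node_mask = np.asarray(self.node_mask, dtype=bool)
        if not self.z_inferior < self.z_superior:
            raise MeshValidationError("z_inferior must be strictly below z_superior")
        n_in = int(self.node_mask.sum())
        if n_in < 1 or n_in >= len(self.node_mask):
            raise MeshValidationError(
                f"sac mask must select a strict non-empty subset (selected {n_in} "
                f"of {len(self.node_mask)})"
            )


def rotate_about_z(points, theta_deg: float) -> np.ndarray:
    """Rotate 3D points about the Z axis by theta_deg (right-handed)."""
    pts = np.asarray(points, dtype=np.float64)
    t = np.deg2rad(float(theta_deg))
    c, s = np.cos(t), np.sin(t)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return pts @ rot.T


def project_silhouette(mesh: SurfaceMesh, rotation_deg: float,
                       z_bins: int = 100) -> tuple[ProjectionCurve, ProjectionCurve]:
    """Silhouette of the rotated node cloud in the (x, z) plane.

    Rotates the nodes by ``rotation_deg`` about Z, drops the depth (y)
    coordinate, partitions z into ``z_bins`` uniform bins, and per non-empty
    bin records the extreme x on each side (right = max, left = min). Empty
    bins are skipped, never interpolated. The mesh must already be centred.
    """
    if z_bins < 1:
        raise MeshValidationError("z_bins must be positive")
    pts = rotate_about_z(mesh.nodes, rotation_deg)
    x, z = pts[:, 0], pts[:, 2]
    z_min, z_max = float(z.min()), float(z.max())
    if z_max <= z_min:
        raise MeshValidationError("mesh has no z extent to project")
    width = (z_max - z_min) / z_bins
    idx = np.clip(((z - z_min) / width).astype(np.int64), 0, z_bins - 1)

    hi = np.full(z_bins, -np.inf)
    lo = np.full(z_bins, np.inf)
    np.maximum.at(hi, idx, x)
    np.minimum.at(lo, idx, x)
    occupied = np.flatnonzero(np.isfinite(hi))
    if len(occupied) < 3:
        raise MeshValidationError(
            f"insufficient silhouette resolution: {len(occupied)} non-empty z bins"
        )
    centers = z_min + (occupied + 0.5) * width
    right = ProjectionCurve(rotation_deg, "right", centers, hi[occupied])
    left = ProjectionCurve(rotation_deg, "left", centers, lo[occupied])
    return left, right


def fourier_eval(fit: FourierFit, z) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    i = np.arange(1, fit.n + 1)
    arg = np.multiply.outer(z, i) * fit.w
    return fit.a0 + np.cos(arg) @ fit.a + np.sin(arg) @ fit.b


def fourier_derivatives(fit: FourierFit, z):
    """Analytic (value, d1, d2) of the fitted series at z (term-wise)."""
    z = np.asarray(z, dtype=np.float64)
    i = np.arange(1, fit.n + 1)
    iw = i * fit.w
    arg = np.multiply.outer(z, iw)
    cos, sin = np.cos(arg), np.sin(arg)
    value = fit.a0 + cos @ fit.a + sin @ fit.b
    d1 = -(sin * iw) @ fit.a + (cos * iw) @ fit.b
    d2 = -(cos * iw**2) @ fit.a - (sin * iw**2) @ fit.b
    return value, d1, d2


def _linear_coeffs(z, y, w, n):
    cols = [np.ones_like(z)]
    for i in range(1, n + 1):
        cols.append(np.cos(i * w * z))
    for i in range(1, n + 1):
        cols.append(np.sin(i * w * z))
    design = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return coef


def _residual_and_jac(z, y, n):
    i = np.arange(1, n + 1)

    def resid(p):
        a0, a, b, w = p[0], p[1 : n + 1], p[n + 1 : 2 * n + 1], p[-1]
        arg = np.multiply.outer(z, i) * w
        return a0 + np.cos(arg) @ a + np.sin(arg) @ b - y

    def jac(p):
        a, b, w = p[1 : n + 1], p[n + 1 : 2 * n + 1], p[-1]
        arg = np.multiply.outer(z, i) * w
        cos, sin = np.cos(arg), np.sin(arg)
        dw = (-sin * (z[:, None] * i)) @ a + (cos * (z[:, None] * i)) @ b
        return np.column_stack([np.ones_like(z), cos, sin, dw])

    return resid, jac


def fit_fourier(curve: ProjectionCurve, n_harmonics: int = 7,
                w_multipliers: tuple = (1.0, 0.5, 2.0),
                warm_start: FourierFit | None = None,
                max_nfev: int = 200) -> FourierFit:
    """Nonlinear least-squares Fourier fit of one boundary branch.

    The fundamental frequency w is a fitted parameter initialised to
    2*pi / z-range; the harmonic coefficients are initialised by a linear
    solve at that frequency. Additional restarts at scaled initial
    frequencies (and, if given, a warm start from a previous fit) guard
    against local minima; the best converged candidate wins. Deterministic
    for identical inputs.
    """
    if not (1 <= n_harmonics <= 8):
        raise MeshValidationError("n_harmonics must lie in [1, 8]")
    z, y = curve.z, curve.x
    min_samples = 2 * (2 * n_harmonics + 2)
    if len(z) < min_samples:
        raise MeshValidationError(
            f"need >= {min_samples} samples for {n_harmonics} harmonics (got {len(z)})"
        )
    z_range = float(z.max() - z.min())
    w0 = 2.0 * np.pi / z_range
    resid, jac = _residual_and_jac(z, y, n_harmonics)
    n_par = 2 * n_harmonics + 2
    lb = np.full(n_par, -np.inf)
    ub = np.full(n_par, np.inf)
    lb[-1], ub[-1] = w0 / 50.0, w0 * 50.0

    inits = []
    if warm_start is not None and warm_start.n <= n_harmonics:
        a = np.zeros(n_harmonics)
        b = np.zeros(n_harmonics)
        a[: warm_start.n] = warm_start.a
        b[: warm_start.n] = warm_start.b
        inits.append(np.concatenate([[warm_start.a0], a, b, [warm_start.w]]))
    for m in w_multipliers:
        w_init = float(np.clip(m * w0, lb[-1], ub[-1]))
        coef = _linear_coeffs(z, y, w_init, n_harmonics)
        inits.append(np.concatenate([coef, [w_init]]))

    # Silhouette branches carry binning/discretization error of a few percent
    # of their amplitude; a converged fit at or below that level is accepted
    # without burning the remaining restarts on noise.
    accept_rmse = 0.02 * (float(np.ptp(y)) + 1e-12)
    best = None
    best_rmse = np.inf
    for p0 in inits:
        res = least_squares(resid, p0, jac=jac, bounds=(lb, ub), method="trf",
                            max_nfev=max_nfev)
        rmse = float(np.sqrt(np.mean(res.fun**2)))
        if res.success and rmse < best_rmse:
            best, best_rmse = res, rmse
        if res.success and rmse <= accept_rmse:
            break
    if best is None:
        raise FitError(
            f"Fourier fit failed to converge after {len(inits)} restarts",
            best_rmse=best_rmse,
        )
    p = best.x
    return FourierFit(
        a0=float(p[0]),
        a=p[1 : n_harmonics + 1].copy(),
        b=p[n_harmonics + 1 : 2 * n_harmonics + 1].copy(),
        w=float(p[-1]),
        n=n_harmonics,
        rmse=best_rmse,
    )


def fit_fourier_sweep(curve: ProjectionCurve, n_min: int = 1, n_max: int = 8) -> list[FourierFit]:
    """Fit 1..8 harmonics with warm starts so RMSE is non-increasing in n."""
    fits: list[FourierFit] = []
    prev = None
    for n in range(n_min, n_max + 1):
        f = fit_fourier(curve, n_harmonics=n, warm_start=prev)
        fits.append(f)
        prev = f
    return fits


def _local_extrema(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict-neighbourhood local maxima and minima of a sampled curve."""
    d = np.diff(values)
    sign = np.sign(d)
    # Carry the sign across flat runs so plateaus count once.
    for i in range(1, len(sign)):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    turns = np.flatnonzero(sign[1:] != sign[:-1]) + 1
    maxima = turns[(sign[turns - 1] > 0) & (sign[turns] < 0)]
    minima = turns[(sign[turns - 1] < 0) & (sign[turns] > 0)]
    return maxima, minima


def detect_sac_bounds(fit: FourierFit, z_range: tuple[float, float],
                      grid_points: int = 1024, mode: str = "extrema") -> SacBounds:
    """Locate the inferior/superior sac limits from the fitted series.

    Evaluates the analytic second derivative d2 on a dense grid. The bulge
    apex is the z of maximum |series value|. In ``extrema`` mode (default)
    the limits are the nearest local extrema of d2 of opposite curvature
    sign to the apex — the flanks where the curvature changes from bulge to
    neck. In ``zero_crossings`` mode they are the nearest zeros of d2 (true
    inflection points). A side with no candidate falls back to that end of
    the z-range and is flagged.
    """
    if mode not in ("extrema", "zero_crossings"):
        raise MeshValidationError("mode must be 'extrema' or 'zero_crossings'")
    if grid_points < 500:
        grid_points = 500
    z_lo, z_hi = float(z_range[0]), float(z_range[1])
    if not z_lo < z_hi:
        raise MeshValidationError("z_range must be an increasing interval")
    zs = np.linspace(z_lo, z_hi, grid_points)
    value, _, d2 = fourier_derivatives(fit, zs)
    if float(np.max(np.abs(d2))) < 1e-9:
        raise NoSacDetectedError(
            "second derivative is identically ~0 (straight tube, no sac)"
        )
    apex = int(np.argmax(np.abs(value)))
    kappa = d2[apex]

    if mode == "extrema":
        maxima, minima = _local_extrema(d2)
        # A curvature-change flank must carry curvature of the opposite sign
        # to the bulge apex; ripples on the apex plateau (extrema of the
        # right type but the wrong sign) are not sac limits.
        if kappa < -1e-12:
            cand = maxima[d2[maxima] > 0]
        elif kappa > 1e-12:
            cand = minima[d2[minima] < 0]
        else:
            cand = np.sort(np.concatenate([maxima, minima]))
    else:
        crossings = np.flatnonzero(np.sign(d2[:-1]) * np.sign(d2[1:]) < 0)
        cand = crossings

    below = cand[cand < apex]
    above = cand[cand > apex]
    if len(below):
        z_inf, fb_inf = float(zs[below[-1]]), False
    else:
        z_inf, fb_inf = z_lo, True
    if len(above):
        z_sup, fb_sup = float(zs[above[0]]), False
    else:
        z_sup, fb_sup = z_hi, True
    return SacBounds(z_inf=z_inf, z_sup=z_sup, fallback_inf=fb_inf, fallback_sup=fb_sup)


def isolate_sac(mesh: SurfaceMesh, config: RotationConfig = RotationConfig(),
                n_harmonics: int = 7, z_bins: int = 100,
                mode: str = "extrema", max_failure_frac: float = 0.5) -> SacRegion:
    """Full sac isolation: rotate, project, fit, detect, aggregate.

    The mesh is centred internally (the result is translation invariant).
    Each of the 360/theta_z rotations contributes a left and a right
    boundary curve; per-curve bounds are aggregated by the median across
    all non-fallback detections. Fails if more than ``max_failure_frac``
    of the curves raise fit/detection errors.
    """
    centered, offset = center_at_origin(mesh)
    z = centered.nodes[:, 2]
    z_lo, z_hi = float(z.min()), float(z.max())

    records = []
    failures = []
    for angle in config.angles():
        try:
            left, right = project_silhouette(centered, angle, z_bins=z_bins)
        except (MeshValidationError,) as exc:
            failures.append((float(angle), "both", repr(exc)))
            logger.debug("projection %.3f deg failed: %s", angle, exc)
            continue
        for curve in (left, right):
            try:
                fit = fit_fourier(curve, n_harmonics=n_harmonics)
                bounds = detect_sac_bounds(fit, (z_lo, z_hi), mode=mode)
            except (FitError, NoSacDetectedError, MeshValidationError) as exc:
                failures.append((float(angle), curve.side, repr(exc)))
                logger.debug("curve %.3f/%s failed: %s", angle, curve.side, exc)
                continue
            records.append((float(angle), curve.side, bounds, fit.rmse))
            logger.debug(
                "curve %.3f/%s: z_inf=%.3f%s z_sup=%.3f%s rmse=%.4g",
                angle, curve.side, bounds.z_inf, "*" if bounds.fallback_inf else "",
                bounds.z_sup, "*" if bounds.fallback_sup else "", fit.rmse,
            )

    n_units = 2 * config.n_projections
    if len(failures) > max_failure_frac * n_units:
        raise SacIsolationError(
            f"sac isolation failed: {len(failures)}/{n_units} boundary curves "
            "raised errors", diagnostics=failures,
        )
    inf_vals = [b.z_inf for _, _, b, _ in records if not b.fallback_inf]
    sup_vals = [b.z_sup for _, _, b, _ in records if not b.fallback_sup]
    if not inf_vals or not sup_vals:
        raise SacIsolationError(
            "sac isolation failed: every detection fell back to the mesh ends",
            diagnostics=failures,
        )
    z_inf = float(np.median(inf_vals))
    z_sup = float(np.median(sup_vals))
    if not z_inf < z_sup:
        raise SacIsolationError(
            f"sac isolation failed: degenerate bounds [{z_inf}, {z_sup}]",
            diagnostics=failures,
        )
    mask = (z >= z_inf) & (z <= z_sup)
    per_projection = [(a, s, b.z_inf, b.z_sup) for a, s, b, _ in records]
    return SacRegion(
        z_inferior=z_inf,
        z_superior=z_sup,
        node_mask=mask,
        per_projection_bounds=per_projection,
        offset_applied=offset,
    )
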