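"""Rotation and torsion quantification from segmented velocity data.

The method reduces each short-axis slice to a single angular velocity per
time frame: in-plane velocities (after global-translation removal) are
expressed in cylindrical coordinates about the myocardial mask centroid, the
mask-average rotational component v_phi is divided by the mask's mean radius
R, and the resulting angular velocity omega(t) is integrated over time into
a rotation angle theta(t).  Torsion between an upper (more basal) and lower
(more apical) slice is the rotation-angle difference normalised by the
inter-slice distance h:

    T(t) = (theta_upper(t) - theta_lower(t)) / h        [deg/mm]

with the sign convention that clockwise rotation in the displayed image
(row axis downward) is positive, so normal systolic twist (base clockwise
relative to apex when viewed from the apex) gives positive torsion.

The transmural summary compares the peak endocardial and epicardial torsion
of the same slice pair:

    dT_max  = T_max_endo - T_max_epi
    d%T_max = dT_max / T_max_endo * 100

Peak values are the signed maxima of the curves; endo- and epicardial peaks
occur essentially simultaneously (end-systole), so the maxima are subtracted
directly without temporal alignment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .segmentation import MyoSegmentation
from .velocity_io import SliceSet, TPMSeries

__all__ = [
    "CylindricalFrame",
    "RotationTrace",
    "TorsionCurve",
    "TransmuralSummary",
    "correct_translation",
    "to_cylindrical",
    "mean_radius",
    "angular_velocity",
    "rotation_angle",
    "compute_rotation_trace",
    "torsion_curve",
    "transmural_summary",
    "resample_and_average",
]

LAYERS = ("full", "endo", "epi")


@dataclass
class CylindricalFrame:
    """One frame's velocity field in cylindrical components about ``center``.

    v_r is positive toward the center (contraction), v_phi positive clockwise
    in the displayed image, v_z passed through unchanged.  All in mm/s.
    """

    v_r: np.ndarray
    v_phi: np.ndarray
    v_z: np.ndarray
    center: tuple[float, float]


@dataclass
class RotationTrace:
    """Angular velocity and integrated rotation angle of one slice and layer."""

    omega_deg_s: np.ndarray
    theta_deg: np.ndarray
    radius_mm: np.ndarray
    layer: str
    slice_label: str
    dt_ms: float


@dataclass
class TorsionCurve:
    """Signed torsion (deg/mm) versus time for one slice pair and layer."""

    t_ms: np.ndarray
    values: np.ndarray
    slice_pair: tuple[str, str]
    layer: str
    h_mm: float

    def __post_init__(self) -> None:
        self.t_ms = np.asarray(self.t_ms, dtype=np.float64)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.t_ms.shape != self.values.shape:
            raise ValueError("time grid and torsion values must have equal length")

    @property
    def T_max(self) -> float:
        """Signed maximum of the torsion curve (expected at end-systole)."""
        return float(self.values.max())

    @property
    def t_peak_ms(self) -> float:
        return float(self.t_ms[int(np.argmax(self.values))])


@dataclass
class TransmuralSummary:
    """Absolute and relative endo-epi difference in peak torsion."""

    dT_max: float
    dPctT_max: float


# ---------------------------------------------------------------------------
# velocity-field operations
# ---------------------------------------------------------------------------

def correct_translation(series: TPMSeries, mask_per_frame: np.ndarray) -> TPMSeries:
    """Remove global in-plane translation of the heart.

    Per frame, the myocardial-mask mean of v_x and v_y is subtracted from
    those components everywhere; v_z is untouched.
    """
    masks = np.asarray(mask_per_frame, dtype=bool)
    if masks.shape != (series.n_frames,) + series.shape:
        raise ValueError("mask stack shape must match the series frames")
    v = series.velocity.copy()
    for t in range(series.n_frames):
        m = masks[t]
        if not m.any():
            raise ValueError(f"empty myocardial mask at frame {t}")
        v[0, t] -= v[0, t][m].mean()
        v[1, t] -= v[1, t][m].mean()
    return series.copy_with_velocity(v)


def to_cylindrical(
    v_x: np.ndarray,
    v_y: np.ndarray,
    v_z: np.ndarray,
    center: tuple[float, float],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> CylindricalFrame:
    """Decompose one frame's velocities into cylindrical components.

    ``center`` is (row, col) in pixels.  Offsets are measured in mm using the
    pixel spacing.  Radial velocity is positive toward the center
    (contraction); rotational velocity is positive clockwise in the display
    convention (row axis downward).  A pixel at the exact center gets
    v_r = v_phi = 0.
    """
    rows, cols = v_x.shape
    if not (0 <= center[0] < rows and 0 <= center[1] < cols):
        raise ValueError(f"center {center} outside grid {v_x.shape}")
    rr, cc = np.mgrid[0:rows, 0:cols]
    d_row = (rr - center[0]) * pixel_spacing[0]
    d_col = (cc - center[1]) * pixel_spacing[1]
    r = np.hypot(d_row, d_col)
    with np.errstate(invalid="ignore", divide="ignore"):
        ur, uc = d_row / r, d_col / r
    at_center = r == 0
    ur = np.where(at_center, 0.0, ur)
    uc = np.where(at_center, 0.0, uc)
    # inward radial unit vector = (-uc, -ur); clockwise tangential = (-ur, uc)
    v_r = -(v_x * uc + v_y * ur)
    v_phi = -v_x * ur + v_y * uc
    return CylindricalFrame(v_r=v_r, v_phi=v_phi, v_z=np.asarray(v_z),
                            center=tuple(center))


def mean_radius(
    mask: np.ndarray,
    center: tuple[float, float],
    pixel_spacing: tuple[float, float] = (1.0, 1.0),
) -> float:
    """Mean Euclidean distance (mm) of mask pixel centers to ``center``."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    rr, cc = np.nonzero(mask)
    d_row = (rr - center[0]) * pixel_spacing[0]
    d_col = (cc - center[1]) * pixel_spacing[1]
    return float(np.hypot(d_row, d_col).mean())


def angular_velocity(cyl: CylindricalFrame, mask: np.ndarray, radius_mm: float) -> float:
    """Slice angular velocity in deg/s: mask-mean v_phi over mean radius."""
    if not radius_mm > 0:
        raise ValueError("radius must be positive")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    omega_rad_s = cyl.v_phi[mask].mean() / radius_mm
    return float(np.degrees(omega_rad_s))


def rotation_angle(omega_deg_s: np.ndarray, dt_ms: float) -> np.ndarray:
    """Cumulative rotation angle (deg) by trapezoidal integration; theta[0] = 0."""
    omega = np.asarray(omega_deg_s, dtype=np.float64)
    if omega.size < 2:
        raise ValueError("need at least two angular-velocity samples")
    return cumulative_trapezoid(omega, dx=dt_ms / 1000.0, initial=0.0)


def compute_rotation_trace(
    series: TPMSeries,
    seg: MyoSegmentation,
    layer: str = "full",
) -> RotationTrace:
    """Angular velocity and rotation angle of one slice for one layer.

    The rotation center is the full myocardial mask centroid of each frame;
    the mean radius is recomputed per frame from the selected layer's mask.
    """
    if layer not in LAYERS:
        raise ValueError(f"layer must be one of {LAYERS}")
    omega = np.empty(series.n_frames)
    radii = np.empty(series.n_frames)
    for t in range(series.n_frames):
        full_mask = seg.mask[t]
        if not full_mask.any():
            raise ValueError(f"empty myocardial mask at frame {t}")
        rr, cc = np.nonzero(full_mask)
        center = (rr.mean(), cc.mean())
        lmask = seg.layer_mask(layer, t)
        cyl = to_cylindrical(
            series.velocity[0, t], series.velocity[1, t], series.velocity[2, t],
            center, series.pixel_spacing,
        )
        radii[t] = mean_radius(lmask, center, series.pixel_spacing)
        omega[t] = angular_velocity(cyl, lmask, radii[t])
    theta = rotation_angle(omega, series.dt_ms)
    return RotationTrace(
        omega_deg_s=omega, theta_deg=theta, radius_mm=radii,
        layer=layer, slice_label=series.slice_label, dt_ms=series.dt_ms,
    )


# ---------------------------------------------------------------------------
# torsion curves and summaries
# ---------------------------------------------------------------------------

def _align_traces(upper: RotationTrace, lower: RotationTrace) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample two rotation-angle traces onto a shared (coarsest-dt) grid."""
    if abs(upper.dt_ms - lower.dt_ms) > 0.1 * min(upper.dt_ms, lower.dt_ms):
        raise ValueError(
            f"temporal resolutions differ by more than 10%: "
            f"{upper.dt_ms} vs {lower.dt_ms} ms"
        )
    dt = max(upper.dt_ms, lower.dt_ms)
    t_end = min(
        (len(upper.theta_deg) - 1) * upper.dt_ms,
        (len(lower.theta_deg) - 1) * lower.dt_ms,
    )
    t = np.arange(0.0, t_end + dt / 2, dt)
    th_u = np.interp(t, np.arange(len(upper.theta_deg)) * upper.dt_ms, upper.theta_deg)
    th_l = np.interp(t, np.arange(len(lower.theta_deg)) * lower.dt_ms, lower.theta_deg)
    return t, th_u, th_l


def torsion_curve(
    trace_upper: RotationTrace,
    trace_lower: RotationTrace,
    h_mm: float,
) -> TorsionCurve:
    """Torsion curve T(t) = (theta_upper - theta_lower) / h for a slice pair.

    ``trace_upper`` is the more basal slice.  Positive torsion means the
    basal slice rotates clockwise (display convention) relative to the
    apical slice.
    """
    if not h_mm > 0:
        raise ValueError("inter-slice distance h must be positive")
    t, th_u, th_l = _align_traces(trace_upper, trace_lower)
    if trace_upper.layer != trace_lower.layer:
        raise ValueError("cannot difference traces of different layers")
    return TorsionCurve(
        t_ms=t,
        values=(th_u - th_l) / h_mm,
        slice_pair=(trace_upper.slice_label, trace_lower.slice_label),
        layer=trace_upper.layer,
        h_mm=h_mm,
    )


def transmural_summary(endo_curve: TorsionCurve, epi_curve: TorsionCurve) -> TransmuralSummary:
    """Difference between peak endocardial and epicardial torsion (Eq. deltas).

    Peaks are subtracted directly (no temporal alignment).  The percent form
    is undefined when the endocardial peak is zero; NaN is returned with a
    warning in that case.
    """
    if endo_curve.slice_pair != epi_curve.slice_pair:
        raise ValueError(
            f"curves come from different slice pairs: "
            f"{endo_curve.slice_pair} vs {epi_curve.slice_pair}"
        )
    d = endo_curve.T_max - epi_curve.T_max
    if endo_curve.T_max == 0:
        warnings.warn("endocardial peak torsion is zero; relative transmural "
                      "difference is undefined", stacklevel=2)
        pct = float("nan")
    else:
        pct = d / endo_curve.T_max * 100.0
    return TransmuralSummary(dT_max=d, dPctT_max=pct)


def resample_and_average(
    curves: list[TorsionCurve],
    dt_out_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample torsion curves to a common grid and average point-wise.

    Each curve is linearly interpolated onto a 0-anchored grid with spacing
    ``dt_out_ms``.  Mean and sample SD are computed per grid point over the
    curves whose support covers that point; the grid is truncated where no
    more than half of the curves have support.

    Returns (t_ms, mean, sd).
    """
    if not curves:
        raise ValueError("need at least one curve")
    ends = [c.t_ms[-1] for c in curves]
    t = np.arange(0.0, max(ends) + dt_out_ms / 2, dt_out_ms)
    coverage = np.zeros(len(t), dtype=int)
    stack = np.full((len(curves), len(t)), np.nan)
    for i, c in enumerate(curves):
        covered = t <= c.t_ms[-1] + 1e-9
        stack[i, covered] = np.interp(t[covered], c.t_ms, c.values)
        coverage += covered
    keep = coverage > len(curves) / 2
    # truncate at the first uncovered point rather than leaving gaps
    n_keep = int(np.argmin(keep)) if not keep.all() else len(t)
    t = t[:n_keep]
    stack = stack[:, :n_keep]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if len(curves) > 1 else np.zeros_like(mean)
    return t, mean, np.nan_to_num(sd)


# ---------------------------------------------------------------------------
# slice-set convenience
# ---------------------------------------------------------------------------

def slice_pair_torsion(
    slices: SliceSet,
    segs: dict[str, MyoSegmentation],
    pair: tuple[str, str],
    layers: tuple[str, ...] = LAYERS,
) -> dict[str, TorsionCurve]:
    """Torsion curves for every requested layer of one slice pair.

    ``pair`` is (upper, lower) by slice label; h comes from the slice
    position metadata and is held fixed over the cycle.
    """
    upper, lower = pair
    h = slices.distance_mm(upper, lower)
    out = {}
    for layer in layers:
        tu = compute_rotation_trace(slices.series[upper], segs[upper], layer)
        tl = compute_rotation_trace(slices.series[lower], segs[lower], layer)
        out[layer] = torsion_curve(tu, tl, h)
    return out
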