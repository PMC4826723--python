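"""Synthetic TPM acquisition of a twisting annular phantom with analytic truth.

The phantom mimics the geometry and kinematics that the torsion pipeline is
built for: per short-axis slice an annular "myocardium" (inner radius
r_endo, outer r_epi) rotates with an angular velocity that varies over the
cardiac cycle, across the wall (transmural gradient) and from base to apex
(the source of torsion), superposed with radial contraction, longitudinal
motion, bulk in-plane translation, a first-order eddy-current offset plane,
and Gaussian velocity noise.  The background is static soft tissue so the
eddy-current correction can find stationary pixels; the magnitude image has
three intensity classes (air / soft tissue / heart) so the tissue
classifier is exercised.

Kinematic model
---------------
The angular-velocity waveform is a systolic half-sine followed by an
opposite-sign diastolic half-sine whose amplitude ratio makes the rotation
angle return to zero at the end of the cycle (periodic motion):

    w(t) = sin(pi t / T_sys)                                 t <= T_sys
         = -(T_sys / T_dia) sin(pi (t - T_sys) / T_dia)      otherwise

The local amplitude is linear in radius, with the endocardial edge
(1 + gamma) times the epicardial edge:

    A(r) = A_epi [1 + gamma (r_epi - r) / (r_epi - r_endo)]   [deg/s]

A smooth transmural profile (rather than a step at the centerline) keeps the
velocity field free of discontinuities that spatial low-pass filtering would
smear across the thin endo/epi layers.  Because the angular-velocity
estimator averages v_phi = omega(r) * r over a layer and divides by the
layer's mean radius, the analytically expected ("effective") layer amplitude
is the radius-weighted average

    A_eff = ( integral_a^b A(r) r^2 dr ) / ( (b^3 - a^3)/3 )

over the layer's radial band [a, b]; the ground-truth rotation angle is
theta(t) = A_eff * W(t) with W the time integral of w, and ground-truth
torsion follows by differencing slices and dividing by their separation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np

from .segmentation import (
    ContourPair,
    MyoSegmentation,
    circle_contour,
    extract_centerline,
    label_layers,
    rasterize_and_close,
)
from .velocity_io import SliceSet, TPMSeries

__all__ = [
    "PhantomSlice",
    "PhantomSpec",
    "GroundTruth",
    "default_spec",
    "paired_slice_spec",
    "generate",
    "analytic_contours",
    "analytic_segmentation",
]

# magnitude-image intensity classes (arbitrary units)
_INTENSITY_AIR = 10.0
_INTENSITY_SOFT = 100.0
_INTENSITY_HEART = 200.0
_AIR_BORDER_PX = 10


@dataclass
class PhantomSlice:
    """Geometry and rotation amplitude of one phantom slice."""

    position_mm: float
    r_endo_mm: float
    r_epi_mm: float
    center_px: tuple[float, float]
    amp_epi_deg_s: float  # epicardial-edge peak angular velocity

    def __post_init__(self) -> None:
        if not self.r_endo_mm < self.r_epi_mm:
            raise ValueError("r_endo must be smaller than r_epi")


@dataclass
class PhantomSpec:
    """Full parameterisation of a synthetic TPM acquisition.

    Acquisition defaults mirror a clinical TPM protocol: venc 250 mm/s,
    temporal resolution 21 ms, in-plane pixel 2.2 mm.
    """

    rows: int = 128
    cols: int = 128
    pixel_mm: float = 2.2
    slices: dict[str, PhantomSlice] = field(default_factory=dict)
    t_sys_ms: float = 300.0
    dt_ms: float = 21.0
    n_frames: int = 40
    gamma: float = 0.3  # transmural gradient: endo amplitude = (1+gamma) * epi
    radial_amp_mm_s: float = 5.0
    v_z_amp_mm_s: float = 10.0
    translation_mm_s: tuple[float, float] = (0.0, 0.0)  # (vx, vy) drift of the heart
    eddy_plane: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    noise_sd_mm_s: float = 0.0
    venc_mm_s: float = 250.0
    taper_mm: float = 6.0  # width of the smooth velocity roll-off outside the annulus
    seed: int = 0

    def __post_init__(self) -> None:
        self.eddy_plane = np.asarray(self.eddy_plane, dtype=float).reshape(3, 3)
        if not self.t_sys_ms < self.duration_ms:
            raise ValueError("systole must end before the cycle does")
        for lab, sl in self.slices.items():
            r_max = sl.r_epi_mm + self.taper_mm
            half = min(sl.center_px[0], self.rows - 1 - sl.center_px[0],
                       sl.center_px[1], self.cols - 1 - sl.center_px[1])
            if r_max / self.pixel_mm > half:
                raise ValueError(
                    f"slice {lab!r}: annulus (+taper) of radius {r_max} mm exceeds the grid"
                )

    @property
    def duration_ms(self) -> float:
        return self.n_frames * self.dt_ms

    @property
    def t_dia_ms(self) -> float:
        return self.duration_ms - self.t_sys_ms

    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_ms


def paired_slice_spec(
    delta_omega_deg_s: float,
    h_mm: float,
    gamma: float = 0.0,
    noise_sd_mm_s: float = 0.0,
    seed: int = 0,
    **overrides,
) -> PhantomSpec:
    """Two-slice phantom for parameter-recovery studies.

    The basal slice's epicardial-edge amplitude is ``delta_omega_deg_s`` and
    the apical slice does not rotate, so the base-apex amplitude difference
    is exactly ``delta_omega_deg_s``; slices are ``h_mm`` apart.  Both share
    the annulus r_endo = 15 mm, r_epi = 25 mm on a 96x96 grid of 2 mm pixels.
    """
    slices = {
        "base": PhantomSlice(h_mm, 15.0, 25.0, (48.0, 48.0), delta_omega_deg_s),
        "apex": PhantomSlice(0.0, 15.0, 25.0, (48.0, 48.0), 0.0),
    }
    return PhantomSpec(
        rows=96, cols=96, pixel_mm=2.0, slices=slices, gamma=gamma,
        noise_sd_mm_s=noise_sd_mm_s, seed=seed, **overrides,
    )


def default_spec(**overrides) -> PhantomSpec:
    """Three-slice phantom with realistic base-to-apex counter-rotation."""
    slices = {
        "base": PhantomSlice(60.0, 20.0, 32.0, (64.0, 64.0), 30.0),
        "mid": PhantomSlice(30.0, 18.0, 30.0, (64.0, 64.0), 5.0),
        "apex": PhantomSlice(0.0, 14.0, 26.0, (64.0, 64.0), -20.0),
    }
    return PhantomSpec(slices=slices, **overrides)


# ---------------------------------------------------------------------------
# analytic waveform and layer amplitudes
# ---------------------------------------------------------------------------

def waveform(t_ms: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Dimensionless angular-velocity waveform w(t)."""
    t = np.asarray(t_ms, dtype=float)
    t_sys, t_dia = spec.t_sys_ms, spec.t_dia_ms
    sys_part = np.sin(np.pi * t / t_sys)
    dia_part = -(t_sys / t_dia) * np.sin(np.pi * (t - t_sys) / t_dia)
    return np.where(t <= t_sys, sys_part, dia_part)


def waveform_integral_s(t_ms: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """W(t) = integral of w in seconds; multiplying by A [deg/s] gives theta [deg]."""
    t = np.asarray(t_ms, dtype=float)
    t_sys_s = spec.t_sys_ms / 1000.0
    t_dia_s = spec.t_dia_ms / 1000.0
    w_max = 2.0 * t_sys_s / np.pi
    rising = (t_sys_s / np.pi) * (1.0 - np.cos(np.pi * t / spec.t_sys_ms))
    falling = w_max - (t_sys_s / np.pi) * (
        1.0 - np.cos(np.pi * (t - spec.t_sys_ms) / spec.t_dia_ms)
    )
    del t_dia_s
    return np.where(t <= spec.t_sys_ms, rising, falling)


def _amp_coefficients(sl: PhantomSlice, gamma: float) -> tuple[float, float]:
    """A(r) = c0 + c1 r over the annulus."""
    width = sl.r_epi_mm - sl.r_endo_mm
    c1 = -gamma * sl.amp_epi_deg_s / width
    c0 = sl.amp_epi_deg_s * (1.0 + gamma * sl.r_epi_mm / width)
    return c0, c1


def _layer_band(sl: PhantomSlice, layer: str) -> tuple[float, float]:
    r_mid = 0.5 * (sl.r_endo_mm + sl.r_epi_mm)
    return {
        "full": (sl.r_endo_mm, sl.r_epi_mm),
        "endo": (sl.r_endo_mm, r_mid),
        "epi": (r_mid, sl.r_epi_mm),
    }[layer]


def effective_amplitude(spec: PhantomSpec, slice_label: str, layer: str = "full") -> float:
    """Radius-weighted effective peak angular velocity of a layer, deg/s."""
    sl = spec.slices[slice_label]
    c0, c1 = _amp_coefficients(sl, spec.gamma)
    a, b = _layer_band(sl, layer)
    cube = (b**3 - a**3) / 3.0
    quart = (b**4 - a**4) / 4.0
    return c0 + c1 * quart / cube


@dataclass
class GroundTruth:
    """Closed-form rotation angles and torsion of a phantom specification."""

    spec: PhantomSpec

    def theta_deg(self, slice_label: str, layer: str, t_ms) -> np.ndarray:
        amp = effective_amplitude(self.spec, slice_label, layer)
        return amp * waveform_integral_s(t_ms, self.spec)

    def torsion(self, slice_pair: tuple[str, str], layer: str, t_ms) -> np.ndarray:
        """Analytic torsion T(t) in deg/mm for (upper, lower) slice labels."""
        upper, lower = slice_pair
        for lab in (upper, lower):
            if lab not in self.spec.slices:
                raise KeyError(f"unknown slice {lab!r} in pair {slice_pair}")
        t = np.asarray(t_ms, dtype=float)
        if (t < 0).any() or (t > self.spec.duration_ms).any():
            raise ValueError("time outside the phantom cycle")
        h = abs(
            self.spec.slices[upper].position_mm - self.spec.slices[lower].position_mm
        )
        return (self.theta_deg(upper, layer, t) - self.theta_deg(lower, layer, t)) / h

    def torsion_max(self, slice_pair: tuple[str, str], layer: str = "full") -> float:
        """Peak (signed maximum) of the analytic torsion curve."""
        peak_at_sys = float(self.torsion(slice_pair, layer, self.spec.t_sys_ms))
        return max(peak_at_sys, 0.0)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _support_profile(r_mm: np.ndarray, sl: PhantomSlice, taper_mm: float) -> np.ndarray:
    """Smooth roll-off: 1 inside the annulus (+hold margin), 0 in the background."""
    hold = sl.r_epi_mm + taper_mm / 2.0
    outer = sl.r_epi_mm + taper_mm
    s = np.clip((outer - r_mm) / (outer - hold), 0.0, 1.0)
    return s


def _slice_velocity(spec: PhantomSpec, sl: PhantomSlice, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.rows, spec.cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    d_row = (rr - sl.center_px[0]) * spec.pixel_mm
    d_col = (cc - sl.center_px[1]) * spec.pixel_mm
    r = np.hypot(d_row, d_col)
    with np.errstate(invalid="ignore", divide="ignore"):
        ur, uc = d_row / r, d_col / r
    ur = np.nan_to_num(ur)
    uc = np.nan_to_num(uc)

    c0, c1 = _amp_coefficients(sl, spec.gamma)
    amp = c0 + c1 * np.clip(r, sl.r_endo_mm, sl.r_epi_mm)  # deg/s, clamped profile
    s = _support_profile(r, sl, spec.taper_mm)
    omega = np.deg2rad(amp) * s  # rad/s
    v_phi_field = omega * r  # mm/s, peak tangential speed map

    w = waveform(spec.times_ms(), spec)  # (T,)
    v = np.zeros((3, spec.n_frames, rows, cols))
    # rotation: clockwise tangential unit vector is (-ur, uc) in (vx, vy)
    v[0] += w[:, None, None] * (v_phi_field * -ur)[None]
    v[1] += w[:, None, None] * (v_phi_field * uc)[None]
    # radial contraction: inward unit vector is (-uc, -ur)
    v[0] += w[:, None, None] * (spec.radial_amp_mm_s * s * -uc)[None]
    v[1] += w[:, None, None] * (spec.radial_amp_mm_s * s * -ur)[None]
    # longitudinal motion, uniform over the moving tissue
    v[2] += w[:, None, None] * (spec.v_z_amp_mm_s * s)[None]
    # bulk translation of the heart (background stays static)
    v[0] += (spec.translation_mm_s[0] * s)[None]
    v[1] += (spec.translation_mm_s[1] * s)[None]
    # eddy-current offset planes, identical in every frame
    plane = (
        spec.eddy_plane[:, 0, None, None]
        + spec.eddy_plane[:, 1, None, None] * cc[None]
        + spec.eddy_plane[:, 2, None, None] * rr[None]
    )
    v += plane[:, None, :, :]
    if spec.noise_sd_mm_s > 0:
        v += rng.normal(0.0, spec.noise_sd_mm_s, size=v.shape)
    return v


def _slice_magnitude(spec: PhantomSpec, sl: PhantomSlice, rng: np.random.Generator) -> np.ndarray:
    rows, cols = spec.rows, spec.cols
    rr, cc = np.mgrid[0:rows, 0:cols]
    r = np.hypot(
        (rr - sl.center_px[0]) * spec.pixel_mm, (cc - sl.center_px[1]) * spec.pixel_mm
    )
    img = np.full((rows, cols), _INTENSITY_SOFT)
    border = (
        (rr < _AIR_BORDER_PX)
        | (rr >= rows - _AIR_BORDER_PX)
        | (cc < _AIR_BORDER_PX)
        | (cc >= cols - _AIR_BORDER_PX)
    )
    img[border] = _INTENSITY_AIR
    img[r <= sl.r_epi_mm + spec.taper_mm] = _INTENSITY_HEART
    img += rng.normal(0.0, 2.0, size=img.shape)
    return np.broadcast_to(img, (spec.n_frames, rows, cols)).copy()


def generate(spec: PhantomSpec) -> tuple[SliceSet, GroundTruth]:
    """Generate the phantom acquisition and its analytic ground truth.

    Output is bit-reproducible for a fixed seed; slices are generated in
    sorted label order so adding a slice does not change the others' noise.
    """
    series = {}
    for lab in sorted(spec.slices):
        # independent child seeds keep slices decoupled and reproducible
        lab_key = zlib.crc32(lab.encode()) & 0x7FFFFFFF
        rng = np.random.default_rng(np.random.SeedSequence((spec.seed, lab_key)))
        sl = spec.slices[lab]
        series[lab] = TPMSeries(
            slice_label=lab,
            magnitude=_slice_magnitude(spec, sl, rng),
            velocity=_slice_velocity(spec, sl, rng),
            pixel_spacing=(spec.pixel_mm, spec.pixel_mm),
            dt_ms=spec.dt_ms,
            slice_position_mm=sl.position_mm,
            venc_mm_s=spec.venc_mm_s,
        )
    return SliceSet(series=series), GroundTruth(spec=spec)


def analytic_contours(spec: PhantomSpec, slice_label: str, frame_index: int = 0) -> ContourPair:
    """Exact circular epi/endo contours of one phantom slice (static geometry)."""
    sl = spec.slices[slice_label]
    return ContourPair(
        epi=circle_contour(sl.center_px, sl.r_epi_mm / spec.pixel_mm),
        endo=circle_contour(sl.center_px, sl.r_endo_mm / spec.pixel_mm),
        frame_index=frame_index,
    )


def analytic_segmentation(spec: PhantomSpec, slice_label: str) -> MyoSegmentation:
    """Segmentation built from the analytic contours at every frame.

    Bypasses contour propagation: the phantom's annulus geometry is static,
    so the exact circles are valid at all frames.
    """
    shape = (spec.rows, spec.cols)
    pair = analytic_contours(spec, slice_label)
    mask = rasterize_and_close(pair, shape)
    centerline = extract_centerline(mask)
    layers = label_layers(mask, centerline, pair)
    n = spec.n_frames
    return MyoSegmentation(
        contours=[replace(pair, frame_index=t) for t in range(n)],
        mask=np.broadcast_to(mask, (n,) + shape).copy(),
        centerline=np.broadcast_to(centerline, (n,) + shape).copy(),
        layer_map=np.broadcast_to(layers, (n,) + shape).copy(),
    )
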