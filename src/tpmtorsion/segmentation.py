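"""Semi-automatic myocardium segmentation for short-axis velocity cines.

One pair of manual epicardial/endocardial contours, drawn at a systolic
frame, is (optionally) refined by an active-contour model driven by the
in-plane velocity field and then propagated to every other frame by
integrating vertex trajectories through the velocity field with a
Runge–Kutta scheme.  Per frame, the contour pair is rasterized into an
annular myocardial mask (smoothed by morphological closing), the mask
centerline is extracted by topology-preserving thinning, and the mask is
split into an endocardial layer (between endocardium and centerline) and an
epicardial layer (between centerline and epicardium).

Coordinates follow the package convention: 0-based (row, col) pixel indices,
row increasing downward.  Contours are arrays of shape (n_vertices, 2).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage.draw import polygon2mask
from skimage.measure import label as cc_label
from skimage.morphology import skeletonize

from .velocity_io import TPMSeries

__all__ = [
    "ContourPair",
    "MyoSegmentation",
    "refine_contours",
    "propagate_contours",
    "rasterize_and_close",
    "extract_centerline",
    "label_layers",
    "segment_series",
    "load_contours",
    "save_contours",
]

# layer-map codes
BACKGROUND, ENDO, EPI = 0, 1, 2

N_CONTOUR_VERTICES = 100


class ContourError(ValueError):
    """Invalid or degenerate contour geometry."""


def _as_polygon(vertices: np.ndarray) -> Polygon:
    return Polygon([(c, r) for r, c in vertices])


def resample_closed_contour(vertices: np.ndarray, n: int = N_CONTOUR_VERTICES) -> np.ndarray:
    """Resample a closed polygon to ``n`` vertices equally spaced in arc length."""
    pts = np.asarray(vertices, dtype=np.float64)
    closed = np.vstack([pts, pts[:1]])
    seg = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ContourError("contour has zero perimeter")
    target = np.linspace(0.0, total, n, endpoint=False)
    out = np.empty((n, 2))
    out[:, 0] = np.interp(target, s, closed[:, 0])
    out[:, 1] = np.interp(target, s, closed[:, 1])
    return out


@dataclass
class ContourPair:
    """Closed epicardial and endocardial polygons at one time frame.

    Vertices are float (row, col) pixel coordinates.  The endocardial contour
    must lie strictly inside the epicardial one and both must be simple
    (non-self-intersecting).
    """

    epi: np.ndarray
    endo: np.ndarray
    frame_index: int = 0

    def __post_init__(self) -> None:
        self.epi = np.asarray(self.epi, dtype=np.float64)
        self.endo = np.asarray(self.endo, dtype=np.float64)
        for name, poly in (("epi", self.epi), ("endo", self.endo)):
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ContourError(f"{name} contour must be (n>=3, 2) vertices")

    def validate(self) -> None:
        p_epi, p_endo = _as_polygon(self.epi), _as_polygon(self.endo)
        for name, p in (("epi", p_epi), ("endo", p_endo)):
            if not p.is_valid:
                raise ContourError(f"{name} contour is self-intersecting")
            if p.area <= 0:
                raise ContourError(f"{name} contour has zero area")
        if not p_epi.contains(p_endo):
            raise ContourError("endocardial contour is not strictly inside epicardial")

    def resampled(self, n: int = N_CONTOUR_VERTICES) -> "ContourPair":
        return ContourPair(
            epi=resample_closed_contour(self.epi, n),
            endo=resample_closed_contour(self.endo, n),
            frame_index=self.frame_index,
        )


def circle_contour(center_rc: tuple[float, float], radius_px: float, n: int = N_CONTOUR_VERTICES) -> np.ndarray:
    """Closed circular contour (row, col vertices), clockwise in display."""
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r0, c0 = center_rc
    return np.column_stack([r0 + radius_px * np.sin(ang), c0 + radius_px * np.cos(ang)])


# ---------------------------------------------------------------------------
# contour JSON interchange
# ---------------------------------------------------------------------------

def save_contours(pair: ContourPair, path) -> None:
    Path(path).write_text(
        json.dumps(
            {
                "frame_index": pair.frame_index,
                "epi": pair.epi.tolist(),
                "endo": pair.endo.tolist(),
            },
            indent=1,
        )
    )


def load_contours(path) -> ContourPair:
    d = json.loads(Path(path).read_text())
    return ContourPair(
        epi=np.asarray(d["epi"], dtype=float),
        endo=np.asarray(d["endo"], dtype=float),
        frame_index=int(d.get("frame_index", 0)),
    )


# ---------------------------------------------------------------------------
# active-contour refinement
# ---------------------------------------------------------------------------

def _snake_system(n: int, alpha: float, beta: float, gamma: float) -> np.ndarray:
    """Inverse of the implicit internal-energy update matrix for a closed snake."""
    d2 = np.zeros(n)
    d2[[0, 1, -1]] = [-2.0, 1.0, 1.0]
    d4 = np.zeros(n)
    d4[[0, 1, 2, -2, -1]] = [6.0, -4.0, 1.0, 1.0, -4.0]
    first_row = gamma * (-alpha * d2 + beta * d4)
    first_row[0] += 1.0
    M = np.empty((n, n))
    for i in range(n):
        M[i] = np.roll(first_row, i)
    return np.linalg.inv(M)


def _external_force_field(series: TPMSeries, frame: int, sigma: float = 2.0) -> np.ndarray:
    """Force field (2, rows, cols) = gradient of the squared edge strength of |v_inplane|.

    The in-plane speed image is Gaussian-smoothed; its gradient-magnitude
    squared forms an edge map whose gradient attracts the snake to velocity
    edges.  The field is normalised to a maximum magnitude of 1 px.
    """
    speed = np.hypot(series.velocity[0, frame], series.velocity[1, frame])
    speed = ndimage.gaussian_filter(speed, sigma)
    gy, gx = np.gradient(speed)
    edge = gx**2 + gy**2
    fy, fx = np.gradient(ndimage.gaussian_filter(edge, sigma))
    force = np.stack([fy, fx])  # (d_row, d_col)
    mx = np.abs(force).max()
    if mx > 0:
        force /= mx
    return force


def _sample_field(field: np.ndarray, pts: np.ndarray) -> np.ndarray:
    """Bilinear sample of a (k, rows, cols) field at (n, 2) row/col points -> (n, k)."""
    coords = pts.T  # (2, n)
    return np.stack(
        [ndimage.map_coordinates(f, coords, order=1, mode="nearest") for f in field],
        axis=1,
    )


def _evolve_snake(
    vertices: np.ndarray,
    force: np.ndarray,
    alpha: float,
    beta: float,
    gamma: float,
    w_ext: float,
    max_iter: int,
    tol_px: float,
) -> np.ndarray:
    x = resample_closed_contour(vertices, N_CONTOUR_VERTICES)
    inv = _snake_system(len(x), alpha, beta, gamma)
    for _ in range(max_iter):
        f = _sample_field(force, x) * w_ext
        x_new = inv @ (x + gamma * f)
        disp = np.max(np.linalg.norm(x_new - x, axis=1))
        x = x_new
        if _shoelace_area(x) < 10.0:
            raise ContourError("active contour collapsed (area < 10 px^2)")
        if disp < tol_px:
            break
    return x


def _shoelace_area(vertices: np.ndarray) -> float:
    r, c = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1)))


def refine_contours(
    initial: ContourPair,
    series: TPMSeries,
    alpha: float = 0.1,
    beta: float = 0.1,
    gamma: float = 1.0,
    w_ext: float = 1.0,
    sigma: float = 2.0,
    max_iter: int = 300,
    tol_px: float = 0.1,
) -> ContourPair:
    """Refine manual contours with an active-contour (snake) model.

    The external force is the gradient of an edge map built from the in-plane
    velocity magnitude at the drawing frame; internal tension (``alpha``) and
    rigidity (``beta``) keep the contour smooth.  Iteration stops when the
    largest vertex displacement falls below ``tol_px`` or after ``max_iter``
    iterations.
    """
    initial.validate()
    force = _external_force_field(series, initial.frame_index, sigma=sigma)
    last_valid = initial
    try:
        epi = _evolve_snake(initial.epi, force, alpha, beta, gamma, w_ext, max_iter, tol_px)
        endo = _evolve_snake(initial.endo, force, alpha, beta, gamma, w_ext, max_iter, tol_px)
        refined = ContourPair(epi=epi, endo=endo, frame_index=initial.frame_index)
        refined.validate()
    except ContourError as exc:
        raise ContourError(f"refinement failed ({exc}); last valid state returned "
                           f"has frame_index {last_valid.frame_index}") from exc
    return refined


# ---------------------------------------------------------------------------
# velocity-field contour propagation
# ---------------------------------------------------------------------------

def _velocity_px_per_frame(series: TPMSeries) -> np.ndarray:
    """In-plane velocity converted to pixel displacement per frame interval.

    Returns (2, frames, rows, cols) in (row, col) order.
    """
    dt_s = series.dt_ms / 1000.0
    v_row = series.velocity[1] * dt_s / series.pixel_spacing[0]
    v_col = series.velocity[0] * dt_s / series.pixel_spacing[1]
    return np.stack([v_row, v_col])


def _sample_flow(flow: np.ndarray, t_frame: float, pts: np.ndarray) -> np.ndarray:
    """Sample the flow field at fractional frame time (cyclic) and points (n, 2)."""
    n_frames = flow.shape[1]
    t = t_frame % n_frames
    k0 = int(np.floor(t)) % n_frames
    k1 = (k0 + 1) % n_frames
    frac = t - np.floor(t)
    f0 = _sample_field(flow[:, k0], pts)
    if frac == 0:
        return f0
    f1 = _sample_field(flow[:, k1], pts)
    return (1 - frac) * f0 + frac * f1


def _rk_step(flow: np.ndarray, t: float, pts: np.ndarray, h: float, order: int) -> np.ndarray:
    if order == 2:
        k1 = _sample_flow(flow, t, pts)
        k2 = _sample_flow(flow, t + h / 2, pts + h / 2 * k1)
        return pts + h * k2
    k1 = _sample_flow(flow, t, pts)
    k2 = _sample_flow(flow, t + h / 2, pts + h / 2 * k1)
    k3 = _sample_flow(flow, t + h / 2, pts + h / 2 * k2)
    k4 = _sample_flow(flow, t + h, pts + h * k3)
    return pts + h / 6 * (k1 + 2 * k2 + 2 * k3 + k4)


def _advect_contour(
    vertices: np.ndarray,
    flow: np.ndarray,
    t_frame: float,
    h: float,
    shape: tuple[int, int],
    rk_order: int,
) -> np.ndarray:
    pts = _rk_step(flow, t_frame, vertices, h, rk_order)
    lo = np.zeros(2)
    hi = np.array(shape, dtype=float) - 1
    if (pts < lo).any() or (pts > hi).any():
        warnings.warn("contour vertex left the image during propagation; clamped",
                      stacklevel=3)
        pts = np.clip(pts, lo, hi)
    pts = resample_closed_contour(pts, N_CONTOUR_VERTICES)
    if not _as_polygon(pts).is_valid:
        warnings.warn("contour self-intersected during propagation; repaired by "
                      "equal-arc-length resampling", stacklevel=3)
        pts = resample_closed_contour(pts, N_CONTOUR_VERTICES)
    return pts


def propagate_contours(
    start: ContourPair,
    series: TPMSeries,
    rk_order: int = 4,
) -> list[ContourPair]:
    """Propagate one contour pair to all frames through the velocity field.

    Vertices are advected with a Runge–Kutta integrator (4th order by
    default, 2nd selectable) using bilinear spatial interpolation and linear
    temporal interpolation of the in-plane velocity field; the field is
    treated as periodic over the cardiac cycle.  Frames after the drawing
    frame are reached by forward integration, earlier frames by backward
    integration.  Contours are resampled to equal arc length after every
    step.
    """
    if rk_order not in (2, 4):
        raise ValueError("rk_order must be 2 or 4")
    n_frames = series.n_frames
    if not 0 <= start.frame_index < n_frames:
        raise ValueError(f"start frame {start.frame_index} outside [0, {n_frames})")
    start.validate()
    flow = _velocity_px_per_frame(series)
    shape = series.shape

    result: list[ContourPair | None] = [None] * n_frames
    start_rs = start.resampled()
    result[start.frame_index] = start_rs

    for direction in (+1, -1):
        epi = start_rs.epi.copy()
        endo = start_rs.endo.copy()
        t = float(start.frame_index)
        steps = (n_frames - 1 - start.frame_index) if direction > 0 else start.frame_index
        for _ in range(steps):
            epi = _advect_contour(epi, flow, t, float(direction), shape, rk_order)
            endo = _advect_contour(endo, flow, t, float(direction), shape, rk_order)
            t += direction
            result[int(round(t))] = ContourPair(
                epi=epi.copy(), endo=endo.copy(), frame_index=int(round(t))
            )
    return result  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# rasterization, centerline, layer labelling
# ---------------------------------------------------------------------------

def rasterize_and_close(contours: ContourPair, shape: tuple[int, int]) -> np.ndarray:
    """Annular myocardial mask between the contour pair, morphologically closed.

    Pixels whose centers are inside the epicardial polygon and outside the
    endocardial polygon form the raw mask; a binary closing with a 3x3
    structuring element smooths the border without filling the cavity.
    """
    for name, poly in (("epi", contours.epi), ("endo", contours.endo)):
        if _shoelace_area(poly) <= 0:
            raise ContourError(f"{name} contour has zero area; mask would be empty")
    epi_mask = polygon2mask(shape, contours.epi)
    endo_mask = polygon2mask(shape, contours.endo)
    mask = epi_mask & ~endo_mask
    if not mask.any():
        raise ContourError("contours rasterize to an empty mask")
    structure = np.ones((3, 3), dtype=bool)
    # a 3x3 closing smooths the border and bridges pinch points without
    # being able to fill the (much larger) endocardial cavity
    return ndimage.binary_closing(mask, structure=structure)


def _count_holes(mask: np.ndarray) -> int:
    """Number of background components fully enclosed by the mask (4-connectivity)."""
    padded = np.pad(~mask, 1, constant_values=True)
    bg = cc_label(padded, connectivity=1)
    border_label = bg[0, 0]
    return len(set(np.unique(bg)) - {0, border_label})


def extract_centerline(mask: np.ndarray) -> np.ndarray:
    """One-pixel-wide, topology-preserving skeleton of an annular mask.

    Requires the mask to be a single 8-connected component with exactly one
    hole; the skeleton of such an annulus is a single closed loop.
    """
    mask = np.asarray(mask, dtype=bool)
    n_comp = cc_label(mask, connectivity=2).max()
    if n_comp != 1:
        raise ValueError(f"mask has {n_comp} connected components; need exactly 1")
    n_holes = _count_holes(mask)
    if n_holes != 1:
        raise ValueError(
            f"mask has {n_holes} holes; an annular myocardium must have exactly 1"
        )
    return skeletonize(mask)


def label_layers(
    mask: np.ndarray,
    centerline: np.ndarray,
    contours: ContourPair | None = None,
) -> np.ndarray:
    """Split the myocardial mask into endocardial and epicardial layers.

    Pixels inside the centerline loop are endocardial, outside epicardial;
    centerline pixels are assigned to the epicardial layer (declared
    tie-break).  Returns an int8 map with codes 0 = background, 1 = endo,
    2 = epi.
    """
    centerline = np.asarray(centerline, dtype=bool)
    filled = ndimage.binary_fill_holes(centerline)
    if filled.sum() <= centerline.sum():
        raise ValueError("centerline is not a closed loop; cannot split layers")
    inside = filled & ~centerline
    layer = np.zeros(mask.shape, dtype=np.int8)
    layer[mask & inside] = ENDO
    layer[mask & ~inside] = EPI
    return layer


# ---------------------------------------------------------------------------
# whole-series segmentation
# ---------------------------------------------------------------------------

@dataclass
class MyoSegmentation:
    """Per-frame contours, masks, centerlines and endo/epi layer maps."""

    contours: list[ContourPair]
    mask: np.ndarray  # (frames, rows, cols) bool
    centerline: np.ndarray  # (frames, rows, cols) bool
    layer_map: np.ndarray  # (frames, rows, cols) int8

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.centerline = np.asarray(self.centerline, dtype=bool)
        self.layer_map = np.asarray(self.layer_map, dtype=np.int8)

    @property
    def n_frames(self) -> int:
        return self.mask.shape[0]

    def layer_mask(self, layer: str, frame: int) -> np.ndarray:
        """Boolean mask of ``layer`` in {"full", "endo", "epi"} at ``frame``."""
        if layer == "full":
            return self.mask[frame]
        code = {"endo": ENDO, "epi": EPI}[layer]
        return self.layer_map[frame] == code


def segment_series(
    series: TPMSeries,
    initial: ContourPair,
    refine: bool = False,
    rk_order: int = 4,
    **snake_kwargs,
) -> MyoSegmentation:
    """Run the full segmentation chain on one slice.

    Optionally refines the manual contours with the active-contour model,
    propagates them to all frames, and derives mask / centerline / layer map
    per frame.
    """
    pair = refine_contours(initial, series, **snake_kwargs) if refine else initial
    contours = propagate_contours(pair, series, rk_order=rk_order)
    shape = series.shape
    masks = np.zeros((series.n_frames,) + shape, dtype=bool)
    centerlines = np.zeros_like(masks)
    layers = np.zeros((series.n_frames,) + shape, dtype=np.int8)
    for t, cp in enumerate(contours):
        masks[t] = rasterize_and_close(cp, shape)
        centerlines[t] = extract_centerline(masks[t])
        layers[t] = label_layers(masks[t], centerlines[t], cp)
    return MyoSegmentation(contours=contours, mask=masks, centerline=centerlines,
                           layer_map=layers)
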