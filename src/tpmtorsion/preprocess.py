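"""Velocity preprocessing: eddy-current baseline correction and noise suppression.

Phase-contrast velocity maps carry a spatially slowly varying velocity offset
caused by residual eddy currents.  Following standard practice the offset is
modelled as a first-order (planar) function of image position per velocity
component, estimated from pixels that are demonstrably stationary:

1. the user outlines a rectangular region of interest (ROI) around the heart;
2. outside that ROI, soft tissue is located by fitting a three-class Gaussian
   mixture (background / soft tissue / solid tissue) to the magnitude
   histogram and keeping the middle-mean class;
3. soft-tissue pixels whose temporal velocity standard deviation is below a
   threshold (default 5 mm/s) in all three components are declared
   stationary;
4. an ordinary least-squares plane is fitted per component to the time-mean
   velocity of the stationary pixels and subtracted everywhere.

A 3x3 spatial low-pass filter (mean by default, median selectable) then
suppresses pixel noise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .velocity_io import TPMSeries

__all__ = [
    "StationaryMask",
    "EddyPlane",
    "classify_soft_tissue",
    "detect_stationary",
    "fit_eddy_plane",
    "correct_eddy",
    "smooth_velocity",
    "preprocess_series",
]

DEFAULT_SD_THRESHOLD_MM_S = 5.0


class DegenerateMixtureError(RuntimeError):
    """Raised when the tissue-class mixture collapses; advise a manual threshold."""


@dataclass
class StationaryMask:
    """Boolean map of stationary soft-tissue pixels used for the baseline fit."""

    mask: np.ndarray
    roi: tuple[int, int, int, int]
    sd_threshold_mm_s: float = DEFAULT_SD_THRESHOLD_MM_S

    @property
    def n_pixels(self) -> int:
        return int(np.count_nonzero(self.mask))


@dataclass
class EddyPlane:
    """First-order baseline v̂_c(row, col) = a_c + b_c*col + c_c*row per component.

    ``coef`` has shape (3, 3): one (a, b, c) triple per velocity component,
    in mm/s and mm/s per pixel.
    """

    coef: np.ndarray

    def evaluate(self, shape: tuple[int, int]) -> np.ndarray:
        """Evaluate the three planes on a (rows, cols) grid -> (3, rows, cols)."""
        rows, cols = np.mgrid[0 : shape[0], 0 : shape[1]]
        a = self.coef[:, 0, None, None]
        b = self.coef[:, 1, None, None]
        c = self.coef[:, 2, None, None]
        return a + b * cols[None] + c * rows[None]


def _roi_slices(roi: tuple[int, int, int, int]) -> tuple[slice, slice]:
    r0, c0, r1, c1 = roi
    return slice(r0, r1), slice(c0, c1)


def classify_soft_tissue(
    magnitude_frame: np.ndarray,
    roi: tuple[int, int, int, int],
    random_state: int = 0,
) -> np.ndarray:
    """Locate soft tissue outside the heart ROI on a magnitude image.

    Fits a three-class Gaussian mixture (background, soft tissue, solid
    tissue) to the magnitude-intensity histogram and returns the pixels
    outside ``roi`` whose maximum-posterior class is the middle-mean one.

    Parameters
    ----------
    magnitude_frame : ndarray (rows, cols)
    roi : (row0, col0, row1, col1)
        Rectangle around the heart (half-open, 0-based); excluded from the
        search.
    random_state : int
        Seed for the mixture initialisation.

    Returns
    -------
    ndarray of bool, True on soft-tissue pixels (always False inside ``roi``).
    """
    from sklearn.mixture import GaussianMixture

    img = np.asarray(magnitude_frame, dtype=np.float64)
    rows, cols = img.shape
    r0, c0, r1, c1 = roi
    if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
        raise ValueError(f"ROI {roi} not inside image of shape {img.shape}")
    outside = np.ones_like(img, dtype=bool)
    outside[_roi_slices(roi)] = False
    values = img[outside]
    if values.size < 300:
        raise ValueError(
            f"only {values.size} pixels outside the heart ROI; need >= 300 "
            "for tissue classification"
        )
    all_values = img.reshape(-1, 1)
    rng = np.float64(img.max() - img.min())
    if rng == 0:
        raise DegenerateMixtureError(
            "magnitude image is constant outside the ROI; tissue classes are "
            "inseparable — supply a manual threshold instead"
        )
    gmm = GaussianMixture(
        n_components=3,
        covariance_type="full",
        max_iter=500,
        tol=1e-6,
        random_state=random_state,
        init_params="kmeans",
    )
    # fit on the whole image so all three tissue classes are represented,
    # then report membership only outside the heart ROI
    gmm.fit(all_values)
    means = np.sort(gmm.means_.ravel())
    if np.min(np.diff(means)) < 0.01 * rng:
        raise DegenerateMixtureError(
            f"mixture class means {means} are separated by less than 1% of the "
            "intensity range; classification is degenerate — supply a manual "
            "threshold instead"
        )
    middle = int(np.argsort(gmm.means_.ravel())[1])
    labels = gmm.predict(values.reshape(-1, 1))
    mask = np.zeros_like(img, dtype=bool)
    mask[outside] = labels == middle
    return mask


def temporal_sd(series: TPMSeries) -> np.ndarray:
    """Per-pixel temporal standard deviation of each velocity component (3, R, C)."""
    return series.velocity.std(axis=1)


def detect_stationary(
    series: TPMSeries,
    soft_mask: np.ndarray,
    threshold_mm_s: float = DEFAULT_SD_THRESHOLD_MM_S,
    roi: tuple[int, int, int, int] = (0, 0, 0, 0),
) -> StationaryMask:
    """Keep soft-tissue pixels whose velocity SD over time is below threshold.

    A pixel is stationary iff the temporal standard deviation of each of
    v_x, v_y, v_z is strictly below ``threshold_mm_s`` and the pixel lies in
    ``soft_mask``.
    """
    soft_mask = np.asarray(soft_mask, dtype=bool)
    if not soft_mask.any():
        raise ValueError("soft-tissue mask is empty")
    sd = temporal_sd(series)
    mask = np.all(sd < threshold_mm_s, axis=0) & soft_mask
    n = int(np.count_nonzero(mask))
    if n < 10:
        raise ValueError(
            f"only {n} stationary pixels found; a first-order baseline fit is "
            "ill-posed with fewer than 10"
        )
    if n < 50:
        warnings.warn(
            f"only {n} stationary pixels found; baseline fit may be unstable",
            stacklevel=2,
        )
    return StationaryMask(mask=mask, roi=roi, sd_threshold_mm_s=threshold_mm_s)


def fit_eddy_plane(series: TPMSeries, stationary: StationaryMask) -> EddyPlane:
    """Ordinary least-squares plane fit per component on stationary pixels.

    The fit uses each stationary pixel's time-averaged velocity, one static
    plane per component for the whole series (eddy-current offsets do not
    vary over the cine).
    """
    mask = stationary.mask
    rr, cc = np.nonzero(mask)
    if rr.size < 10:
        raise ValueError(f"need >= 10 stationary pixels, got {rr.size}")
    design = np.column_stack([np.ones(rr.size), cc.astype(float), rr.astype(float)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("stationary pixels are collinear; plane fit is ill-posed")
    vmean = series.velocity.mean(axis=1)  # (3, rows, cols)
    targets = vmean[:, rr, cc].T  # (n, 3)
    coef, *_ = np.linalg.lstsq(design, targets, rcond=None)
    return EddyPlane(coef=np.ascontiguousarray(coef.T))


def correct_eddy(series: TPMSeries, plane: EddyPlane) -> TPMSeries:
    """Subtract the fitted baseline planes from every frame of every component."""
    baseline = plane.evaluate(series.shape)  # (3, rows, cols)
    return series.copy_with_velocity(series.velocity - baseline[:, None, :, :])


def smooth_velocity(series: TPMSeries, method: str = "mean") -> TPMSeries:
    """Apply a 3x3 spatial low-pass filter to each velocity frame.

    ``method`` selects a 3x3 mean (default) or median filter; edges are
    handled by reflection.  ``method="none"`` returns the series unchanged.
    """
    if method == "none":
        return series
    if method == "mean":
        smoothed = ndimage.uniform_filter(
            series.velocity, size=(1, 1, 3, 3), mode="reflect"
        )
    elif method == "median":
        smoothed = ndimage.median_filter(
            series.velocity, size=(1, 1, 3, 3), mode="reflect"
        )
    else:
        raise ValueError(f"unknown smoothing method {method!r}")
    return series.copy_with_velocity(smoothed)


def preprocess_series(
    series: TPMSeries,
    roi: tuple[int, int, int, int],
    sd_threshold_mm_s: float = DEFAULT_SD_THRESHOLD_MM_S,
    filter_method: str = "mean",
    random_state: int = 0,
) -> tuple[TPMSeries, dict]:
    """Full preprocessing chain: classify, detect, fit, correct, smooth.

    Returns the corrected series and a report dict (stationary pixel count
    and plane coefficients) suitable for JSON serialisation.
    """
    soft = classify_soft_tissue(series.magnitude[0], roi, random_state=random_state)
    stationary = detect_stationary(series, soft, sd_threshold_mm_s, roi=roi)
    plane = fit_eddy_plane(series, stationary)
    corrected = correct_eddy(series, plane)
    corrected = smooth_velocity(corrected, method=filter_method)
    report = {
        "n_stationary_pixels": stationary.n_pixels,
        "sd_threshold_mm_s": sd_threshold_mm_s,
        "plane_coefficients": plane.coef.tolist(),
        "filter": filter_method,
    }
    return corrected, report
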