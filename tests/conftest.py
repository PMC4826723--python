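"""Shared fixtures: small phantoms and a reusable recovery harness."""

from __future__ import annotations

import numpy as np
import pytest

import tpmtorsion as tt
from tpmtorsion.phantom import analytic_segmentation, paired_slice_spec


@pytest.fixture(scope="session")
def clean_phantom():
    """Three-slice noise-free phantom with its analytic ground truth."""
    spec = tt.default_spec(seed=7)
    slices, truth = tt.generate(spec)
    return spec, slices, truth


@pytest.fixture(scope="session")
def clean_base_series(clean_phantom):
    _, slices, _ = clean_phantom
    return slices.series["base"]


def recover_torsion(spec, layers=("full", "endo", "epi"), smooth=True):
    """Generate a two-slice phantom and measure base-apex torsion per layer.

    Returns {layer: (recovered_T_max, analytic_T_max)}.
    """
    slices, truth = tt.generate(spec)
    segs = {lab: analytic_segmentation(spec, lab) for lab in slices.series}
    for lab, series in slices.series.items():
        if smooth:
            series = tt.smooth_velocity(series)
        slices.series[lab] = tt.correct_translation(series, segs[lab].mask)
    pair = ("base", "apex")
    h = slices.distance_mm(*pair)
    out = {}
    for layer in layers:
        tu = tt.compute_rotation_trace(slices.series["base"], segs["base"], layer)
        tl = tt.compute_rotation_trace(slices.series["apex"], segs["apex"], layer)
        curve = tt.torsion_curve(tu, tl, h)
        out[layer] = (curve.T_max, truth.torsion_max(pair, layer))
    return out


def rigid_rotation_series(
    omega_deg_s: float = 30.0,
    n_frames: int = 51,
    dt_ms: float = 20.0,
    shape: tuple[int, int] = (96, 96),
    pixel_mm: float = 2.0,
) -> tt.TPMSeries:
    """Whole-image rigid clockwise rotation about the grid center.

    The in-plane velocity is linear in position, so bilinear interpolation
    of the field is exact and integration error isolates the time stepper.
    """
    rows, cols = shape
    center = ((rows - 1) / 2.0, (cols - 1) / 2.0)
    rr, cc = np.mgrid[0:rows, 0:cols]
    d_row = (rr - center[0]) * pixel_mm
    d_col = (cc - center[1]) * pixel_mm
    omega = np.deg2rad(omega_deg_s)
    v_x = np.broadcast_to(-omega * d_row, (n_frames, rows, cols)).copy()
    v_y = np.broadcast_to(omega * d_col, (n_frames, rows, cols)).copy()
    v_z = np.zeros_like(v_x)
    return tt.TPMSeries(
        slice_label="mid",
        magnitude=np.ones((n_frames, rows, cols)),
        velocity=np.stack([v_x, v_y, v_z]),
        pixel_spacing=(pixel_mm, pixel_mm),
        dt_ms=dt_ms,
        slice_position_mm=0.0,
        venc_mm_s=250.0,
    )


__all__ = ["recover_torsion", "rigid_rotation_series", "paired_slice_spec"]
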