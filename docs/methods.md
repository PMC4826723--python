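# Methods

This note documents the models, parameter choices and numerical decisions
behind `tpmtorsion`, and what the phantom-based validation does and does not
demonstrate.

## Data model and conventions

A TPM slice is a magnitude cine plus a three-component velocity cine
(`TPMSeries`).  Conventions, fixed package-wide:

* 0-based (row, col) pixel indices; the row axis increases downward in
  display.
* Velocity component x runs along columns, y along rows, z through-plane;
  units are mm/s, time in ms, distances in mm.
* Stored phase maps to velocity linearly, v = φ/π · venc, the standard
  phase-contrast convention; a scanner using a different dialect must be
  converted on import.
* Rotational velocity v_φ is positive clockwise in the displayed image and
  radial velocity v_r positive toward the center (contraction), so normal
  systolic twist (base clockwise relative to apex, viewed from the apex)
  produces positive torsion.

The container format is a zip of two `.npy` arrays plus JSON metadata with
fixed zip timestamps; writes are byte-deterministic, which makes whole-run
reproducibility testable by file comparison.

## Eddy-current correction

Residual eddy currents add a spatially slowly varying offset to each
velocity component.  The correction assumes the offset is (i) first order
in image position and (ii) constant over the cine, so one plane per
component is fitted by ordinary least squares to the *time-averaged*
velocity of stationary pixels and subtracted from every frame.  Stationary
pixels are the intersection of the soft-tissue class (3-class Gaussian
mixture on the magnitude histogram: background / soft tissue / solid
tissue, middle mean taken, heart ROI excluded) with the per-pixel rule
SD < 5 mm/s over time in all three components.  The intersection is
order-independent, so whether thresholding "precedes" classification is
immaterial.  The mixture is fitted on the whole magnitude histogram (all
three classes must be represented) with k-means initialisation, tolerance
1e-6, at most 500 EM iterations, and a fixed seed; mixtures whose sorted
class means are separated by less than 1% of the intensity range are
rejected as degenerate rather than silently mislabelled.

Fewer than 10 stationary pixels is an error (a 3-parameter plane on fewer
points, or on collinear points, is ill-posed); fewer than 50 warns.

The "low-pass 3×3" noise filter is implemented as a 3×3 spatial mean with
reflected edges — the standard low-pass reading — with a median variant
selectable (`filter_method="median"`) and `"none"` to disable.

## Segmentation

One manual contour pair, drawn at a systolic frame, drives the whole cine.

* **Active-contour refinement** (optional, off by default since manual
  contours may be trusted): a classic snake with periodic second/fourth
  difference internal terms (tension α = 0.1, rigidity β = 0.1, step
  γ = 1.0) and an external force equal to the gradient of the squared edge
  strength of the Gaussian-smoothed (σ = 2 px) in-plane speed image,
  normalised to a maximum of 1 px.  These weights are package defaults, not
  protocol values.  Convergence: max vertex displacement < 0.1 px, cap 300
  iterations; collapse below 10 px² or endo/epi crossing aborts.
* **Propagation**: vertices are advected frame-to-frame through the
  in-plane velocity field with 4th-order Runge–Kutta (RK2 selectable),
  bilinear spatial and linear temporal interpolation, the field treated as
  periodic over the cycle.  Frames after the drawing frame are reached
  forward, earlier frames backward.  Contours are resampled to 100
  equal-arc-length vertices after every step to prevent vertex clustering;
  vertices leaving the grid are clamped with a warning, self-intersections
  are repaired by resampling with a warning.  On a linear (rigid-rotation)
  field bilinear interpolation is exact, so the measured 1e-9 px error
  isolates RK4 truncation; on the periodic phantom, cycle closure is below
  0.5 px.
* **Mask, centerline, layers**: pixels inside the epicardial and outside
  the endocardial polygon (pixel-center test) are closed with a 3×3
  structuring element — enough to bridge pinch points, too small to fill
  the cavity.  The centerline is the topology-preserving thinning skeleton
  (a single loop for an annulus; non-annular masks are rejected with the
  component/hole count).  Pixels inside the centerline loop are
  endocardial, outside epicardial; centerline pixels themselves go to the
  epicardial layer (a declared tie-break affecting ~1–2% of pixels).  The
  centerline is recomputed per frame from that frame's mask.

## Rotation and torsion

Per frame and layer: the rotation center is the full-mask centroid; the
angular velocity is the layer-mask mean of v_φ divided by the layer's mean
radius R (per-layer R is the default and the choice matters for transmural
comparisons — normalising both layers by the whole-mask R is available via
configuration).  R and the centroid are recomputed every frame.  θ(t) is
the cumulative trapezoidal integral of ω with θ(0) = 0, and

    T(t) = (θ_upper(t) − θ_lower(t)) / h

with h taken from slice-position metadata and held fixed (long-axis
shortening is deliberately not modelled; imaging planes are static during
acquisition).  Traces with mismatched temporal resolution (≤10% apart) are
resampled to the coarser grid before differencing.

T_max is the *signed* maximum of T(t) — systolic twist is positive under
the sign convention, and the peak is expected at end-systole — not the
maximum absolute value.  ΔT_max subtracts the two layers' maxima directly
without temporal alignment (endo- and epicardial peaks are concomitant).
Group mean curves resample each curve onto a 0-anchored 5-ms grid; the grid
is truncated once no more than half the curves still have support.

## Phantom

The phantom emulates: an annular myocardium per slice (static geometry);
an angular-velocity waveform A·sin(πt/T_sys) during systole followed by an
opposite-sign diastolic half-sine scaled by T_sys/T_dia so rotation returns
to zero (periodic motion, mimicking untwisting); a transmural amplitude
profile *linear in radius* with the endocardial edge (1+γ) times the
epicardial edge; base-to-apex amplitude differences (the source of
torsion); radial contraction, uniform longitudinal motion, bulk in-plane
translation confined to the moving tissue; static background soft tissue;
first-order eddy offset planes; Gaussian velocity noise of stated SD; and a
three-class magnitude image.  Acquisition defaults mirror a clinical TPM
protocol: venc 250 mm/s, dt 21 ms, 2.2 mm pixels (2.0 mm on the small
recovery grids), 40 frames (~840 ms cycle, T_sys = 300 ms).

A smooth linear transmural profile was chosen over a two-band step because
a velocity discontinuity at the centerline would be smeared asymmetrically
into the two thin layers by the 3×3 low-pass filter, confounding the
transmural comparison with a filtering artifact.  The velocity support
extends ~6 mm beyond the epicardial radius with a smooth roll-off so that
spatial smoothing near the mask border does not mix myocardial velocities
with zeros.

Because the angular-velocity estimator weighs pixels by radius (mean v_φ
over mean R), the analytic layer ground truth uses the radius-weighted
effective amplitude  A_eff = ∫ A(r) r² dr / ((b³−a³)/3)  over the layer's
radial band, with the endo/epi split at the mid radius (where the thinning
centerline of an annulus lies).  Ground-truth torsion follows in closed
form; its peak sits exactly at end-systole.

What passing phantom tests do **not** show: robustness to through-plane
motion of tissue (the annulus geometry is static), partial-volume and
flow-related magnitude artifacts, papillary muscles, segmentation ambiguity
at low blood–myocardium contrast, or breathing motion.  Recovery numbers on
real data will be worse than the phantom's ~2% (noise-free) / ~12–15%
(10 mm/s noise) errors.

## Statistics

Group comparisons use Shapiro–Wilk at α = 0.05 on each sample (the choice
of normality test is a package decision); if both pass, Welch's
unequal-variance t-test, otherwise the Wilcoxon rank-sum test, two-sided.
Constant samples are routed to the rank-sum branch (Shapiro–Wilk is
undefined there); two constant samples are an error.  No multiple-testing
correction is applied; p-values are reported raw.  Bland–Altman limits of
agreement are mean ± 1.96·SD (SD with n−1).  The relative-error summary is
the mean over pairs of |difference| / pair mean in percent, with an
alternative |mean difference| / grand mean available — published
scan–rescan error figures do not pin down the formula, so it is explicitly
configurable and the default is declared, not inferred.

Null calibration of the adaptive test (2000 two-sample normal replicates,
n = 15 per group) lands at a 4–5% rejection rate at p < 0.05; the measured
power at a 2-SD shift matches the ~0.96 Welch theory value.

## Problem sizes and determinism

The validation suite uses 96×96 two-slice phantoms (2 mm pixels, 40
frames) for the 27-point recovery grid and 50-seed noise study, and the
128×128 three-slice phantom for end-to-end runs — sizes at which discrete
masks approximate the analytic annuli to ~1–2% while a full grid completes
in seconds.  All randomness flows from explicit integer seeds
(`numpy.random.default_rng`); phantom slices draw from independent child
seeds keyed by slice label so adding a slice does not perturb the others.
Repeated runs with the same configuration produce byte-identical summaries.

## Known limitations

* Long-axis shortening is not corrected; h is fixed by design.
* The centerline is recomputed per frame rather than tracked, so layer
  assignment can flicker by a pixel ring between frames.
* Segmental (AHA) analysis, local shear measures and fully automatic
  segmentation are out of scope.
* Phase wraps (|v| > venc) are not unwrapped; inputs are clipped at ±venc.
* DICOM support covers standard tags plus a documented private block for
  venc/timing; vendor-specific private venc tags are not parsed.
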