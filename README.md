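# tpmtorsion

Quantification of left-ventricular (LV) torsion from tissue phase mapping
(TPM) — phase-contrast cine cardiac MRI that measures myocardial velocity in
three directions at every pixel.  The package is aimed at cardiac-MRI
researchers who acquire short-axis TPM slices at base, mid and apex and want
global and transmural (endocardial / epicardial) torsion curves and peak
biomarkers, plus the cohort statistics to compare them between subject
groups.

## Method

For each short-axis slice the pipeline:

1. **Corrects eddy-current baselines.**  Inside a user rectangle complement,
   soft tissue is found by a 3-class Gaussian mixture on the magnitude
   histogram; soft-tissue pixels with temporal SD(v_x), SD(v_y), SD(v_z)
   all < 5 mm/s are stationary, and a first-order plane
   v̂_c(x, y) = a + b·x + c·y fitted per velocity component to those pixels
   is subtracted from the velocity field.  A 3×3 spatial low-pass filter
   suppresses residual noise.
2. **Segments the myocardium semi-automatically.**  One manual epi/endo
   contour pair (optionally refined by an active-contour model driven by
   the in-plane velocity field) is propagated to all frames by 4th-order
   Runge–Kutta integration of vertex trajectories through the velocity
   field.  The rasterized annular mask is smoothed by morphological closing,
   its centerline extracted by topology-preserving thinning, and pixels
   inside / outside the centerline loop are labelled endocardial /
   epicardial.
3. **Computes rotation and torsion.**  After removing global in-plane
   translation (mask-mean subtraction per frame), velocities are expressed
   in cylindrical coordinates (v_r, v_φ, v_z) about the mask centroid.  The
   slice angular velocity is ω_t = ⟨v_φ⟩ / R with R the mean myocardial
   radius, the rotation angle θ_t its time integral, and torsion between an
   upper and lower slice

       T_t = Δθ_t / h      [°/mm]

   with h the fixed inter-slice distance.  Peak torsion T_max and the
   transmural difference ΔT_max = T_max^endo − T_max^epi (and its percent
   form Δ%T_max = ΔT_max / T_max^endo × 100) summarise each curve; group
   mean curves are built by resampling to a 5-ms grid.
4. **Cohort statistics.**  Welch t-test / Wilcoxon rank-sum (gated by
   Shapiro–Wilk), Pearson correlation, and Bland–Altman agreement with
   limits of agreement mean ± 1.96 SD.

A synthetic rotating-annulus phantom (`tpmtorsion.phantom`) generates
acquisitions with transmural and base-to-apex angular-velocity gradients,
radial contraction, translation, eddy-current offset planes and velocity
noise — with closed-form ground-truth torsion, so every stage is testable
end to end.

## Worked example

Simulate a three-slice phantom and run the base–apex torsion analysis:

```sh
tpm simulate --seed 1 --out demo/sim
tpm torsion --base demo/sim/base.tpm --mid demo/sim/mid.tpm \
    --apex demo/sim/apex.tpm --contours-dir demo/sim \
    --roi 20,20,108,108 --pairs base-apex --out demo/run
```

The summary printed at the end contains (abridged):

```json
"base-apex": {
  "h_mm": 60.0,
  "layers": {
    "full": {"T_max": 0.17926, "t_peak_ms": 315.0},
    "endo": {"T_max": 0.19636, "t_peak_ms": 315.0},
    "epi":  {"T_max": 0.17313, "t_peak_ms": 315.0}
  },
  "dT_max": 0.02324,
  "dPctT_max": 11.83
}
```

Read: over a 60-mm base–apex separation the LV twists to a peak torsion of
0.179 °/mm at end-systole (315 ms); the endocardial layer twists more than
the epicardial one (0.196 vs 0.173 °/mm), a transmural difference of
0.023 °/mm or 11.8% of the endocardial peak — the expected signature of a
positive transmural gradient.  The phantom's analytic ground truth for this
configuration is 0.17901 °/mm for the full wall, so the pipeline recovers
the peak within 0.15%.  `demo/run/curves_base-apex.csv` holds the full
torsion–time curves for all three layers.

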