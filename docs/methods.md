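# Methods

## The phasor transform

Each voxel's decay `v_0 … v_{M−1}`, ordered by contrast time, is mapped to
its normalized discrete Fourier coefficients `G_n + i S_n`, `n = 1 … ⌊M/2⌋`,
with the zeroth-order coefficient (the summed signal, proportional to the
equilibrium magnetization) as the normalizer. Two conventions are fixed
package-wide:

* **Index-based DFT.** The transform runs over the sample *index*, not
  physical time. MOLLI TI grids are strongly non-uniform; taking the DFT
  over the index keeps the transform exactly linear in the decay and
  applies identically to data and reference curves, at the cost of making
  the mono-exponential reference locus depend on the TI grid. That
  dependence is intrinsic: two series sampled differently have different
  reference curves and their Axis1 scales are not comparable.
* **+sin convention.** `S_n` uses `+sin`, so decaying signals populate the
  upper half-plane, matching the fluorescence-lifetime phasor convention.

The transform is a ratio of linear functionals of the decay, which gives the
two load-bearing exact identities:

1. *Chord (convexity) identity.* The phasor of a sum of decays is the
   convex combination of the component phasors weighted by their summed
   intensities. Two-tissue voxels therefore lie on the chord between the
   pure positions; three-tissue mixtures fill the triangle.
2. *Scale invariance.* Multiplying a decay by any positive constant leaves
   its phasor unchanged.

## Inversion-recovery conversion

IR series rise toward an asymptote, so before the transform each voxel is
converted by `D_k = S_last − S_k`, estimating the asymptote with the
longest-TI sample (several times the expected T1 in MOLLI protocols). For a
pure tissue this gives exactly `2(exp(−t_k/T1) − exp(−t_max/T1))`, i.e. a
mono-exponential decay minus a constant. The terminal sample is identically
zero after conversion; it is retained so data and reference curves share one
sample count and harmonic grid. Conversion is guarded against being applied
twice.

A consequence worth noting: simulating the phantom as raw decays with
offset correction, or as IR curves with the standard conversion, produces
*identical* phasors — the converted IR decay is exactly twice the
offset-corrected decay and the transform is scale-invariant. Both simulation
modes are provided and coincide in phasor space for noiseless data.

Input data are assumed phase-sensitive (signed). A polarity-restoration
helper for magnitude-only data (sign flip before each voxel's minimum) is
available but off by default.

## Projection plane and calibration

The 2N-dimensional phasor vectors of three anchor lifetimes (defaults
1.5 s, 1.75 s, 2.0 s: the two tissue T1s plus an in-between value) define an
affine plane; an orthonormal in-plane basis comes from Gram–Schmidt on the
anchor differences, with collinearity rejected at a 1e−10 rank tolerance and
orthonormality maintained to 1e−12. Voxels are projected orthogonally onto
the plane.

The in-plane frame is then fixed by a similarity transform (rotation,
uniform scale, translation, reflection resolved so the anchors have
Axis2 ≥ 0) that pins the two exact lifetime limits: the zero-lifetime phasor
(a delta at the first sample, all `(G_n, S_n) = (1, 0)`) maps to (1, 0) and
the infinite-lifetime phasor (the zero vector) maps to (0, 0). This
calibration was chosen because it is the unique similarity with
coordinate-free anchors, puts Axis1 on a 0–1-like scale, and is exactly
reproducible from the sampling grid alone.

**Limitation.** Any affine recalibration of the plane frame rescales Axis1;
interval thresholds for segmentation are therefore *frame-specific
configuration*, not portable constants. Other implementations that normalize
the frame differently (e.g. without pinning the lifetime limits) will report
different absolute Axis1 values for the same data — with this calibration
and the default MOLLI grid, the pure myocardium/blood clusters of the
default phantom sit at Axis1 = 0.3550/0.2900. Segmentation interval presets
bundled with the package (one for the simulation study, two for patient-style
datasets) illustrate the configuration format; they were defined in a
different frame convention and must be re-calibrated (e.g. from the cluster
endpoints of the dataset at hand, as done in the tests) before being applied
to clouds produced by this package.

In inversion-recovery mode the τ→∞ limit of the *converted* decay is a
linear ramp rather than the zero vector, so the exact (0, 0) endpoint of the
reference curve is realized in plain-decay mode; mono-exponential reference
decays are evaluated in the rescaled form `exp(−(t_k − t_0)/τ)` (exactly
proportional, hence phasor-identical) so extreme grid lifetimes neither
underflow nor overflow.

## Phantom generator

The phantom emulates a short-axis left ventricle: an outer myocardium ring
(T1 = 1.5 s) around a blood disk (T1 = 2.0 s), both with unit equilibrium
signal density, zero signal outside. Geometry is rasterized on a
1000×1000 grid and block-averaged to 21×21 by assigning each fine cell to
the coarse voxel containing its center — unambiguous for the non-integer
1000/21 ratio and exactly count-conserving. Ring radii (0.45/0.30 of the
field of view) are free parameters chosen to fill the grid the way a
short-axis ventricle fills a tight field of view.

Default sampling uses the eight-point MOLLI TI grid
(0.129, 0.209, 1.344, 1.394, 2.494, 2.551, 3.644, 4.807 s). Noise, off by
default, is additive Gaussian with a fixed RNG seed. What the phantom does
*not* emulate: Rician magnitude statistics, coil-sensitivity shading,
within-tissue T1 heterogeneity, through-plane motion, or any acquisition
physics — so passing tests demonstrate the exactness of the geometry-based
machinery, not robustness to every artifact of real scans.

Motion corruption translates the even-numbered frames (1-based, TI-sorted)
by a configurable number of voxels (default experiment: 8, vertical),
zero-filling vacated rows — the simplest model of one abrupt displacement
between interleaved acquisitions.

## Partial-volume unmixing

A fraction library tabulates, at 0.001 resolution by default, the projected
position of every mixture fraction simulated through the identical
mode/conversion as the data. Estimation is nearest-neighbor in (Axis1,
Axis2) with ties broken toward the smaller fraction (determinism) and the
match distance reported for quality control. Along-chord spacing is
intensity-weighted — `w(f) = f·A_myo / (f·A_myo + (1−f)·A_blood)` with `A`
the summed converted pure decays — hence monotone but non-uniform in `f`.
On the noiseless phantom the maximum recovery error is bounded by the
library step (measured: 4.9e−4 at step 1e−3 over the 313 phantom voxels).

## Segmentation

Classes are assigned from Axis1 alone by interval membership; Axis2 is
deliberately unused. Printed-style interval notation `a > Axis1 > b` is
implemented half-open as `(b, a]`: exact-boundary values — measure-zero for
real data — deterministically join the interval they close. Overlapping
intervals are a configuration error; values outside all intervals get the
`other` (background/noise) label.

## Motion scatter index

For a projected cloud and a densely sampled projected reference curve
(≥ 500 points over 0.75–10 s by default), the index is the standard
deviation (ddof = 1; median absolute deviation available as an option) of
the signed minimal point-to-polyline distance — the second-moment summary of
scatter *perpendicular* to the mono-exponential locus, which is the
signature of inter-frame motion. It is reported as a ratio against a
motion-free acquisition of the same anatomy, making it invariant to rigid
in-plane transformations of the frame and insensitive to the absolute noise
level. In the phantom experiment the ROI is the phantom support: the
broadened-ROI option exists for measured data where shifted anatomy must be
captured, but on a synthetic grid it would admit signal-free background
voxels whose noise-only decays dominate the index in both arms.

## Problem sizes and numerical choices

* Phantom: 1000×1000 fine, 21×21 coarse, 8 TIs — the full study condition,
  small enough that every test runs it outright.
* Motion experiment: 20 noise seeds at σ = 0.02 (≈ 1% of the converted
  decay's dynamic range of 2).
* Fit: `scipy.optimize.least_squares` with log-linear initialization,
  bounded rate > 0, 200 function evaluations; failures yield NaN (invalid
  voxel), never an exception, so maps degrade gracefully.
* Tolerances: rank 1e−10, orthogonality 1e−12, chord/convexity assertions
  1e−9–1e−10; all comfortably above double-precision round-off for the
  8-sample, 4-harmonic geometry.

## Known limitations

* Axis1 absolute values are convention-bound (above); only orderings,
  ratios and within-dataset intervals are meaningful.
* The asymptote estimate uses the longest-TI sample; for short final TIs
  (< 3×T1) the residual offset perturbs all phasors systematically.
* Anchor lifetimes are user-chosen; no automated anchor or interval
  selection is provided.
* No Look-Locker T1* correction is applied anywhere; fitted "T1" values on
  converted MOLLI data inherit the corresponding biases of the
  two-parameter model.
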