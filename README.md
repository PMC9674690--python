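# t1phasor

Model-free **full-harmonics phasor analysis** for quantitative T1
relaxometry image series (MOLLI-style inversion recovery), with a virtual
left-ventricle phantom simulator, partial-volume unmixing, phasor-based
segmentation and motion-corruption detection — no curve fitting anywhere in
the core method.

## The problem

Myocardial T1 mapping samples the inversion-recovery curve of every voxel at
a handful of inversion times (TI) and conventionally fits a per-voxel
mono-exponential model. Voxels at the myocardium–blood interface contain
signal from *both* tissues, so their decay is bi-exponential and the fit is
biased; motion between frames corrupts the per-voxel curves in ways a fit
cannot flag. Phasor analysis — standard practice in fluorescence lifetime
imaging — replaces the fit with the discrete Fourier transform of each
voxel's decay, normalized by its zeroth-order coefficient:

    G_n = Σ_k v_k cos(2πnk/M) / Σ_k v_k
    S_n = Σ_k v_k sin(2πnk/M) / Σ_k v_k ,   n = 1 … ⌊M/2⌋

Stacking all `N = ⌊M/2⌋` harmonics embeds each voxel in a 2N-dimensional
phasor space. Because the transform is a ratio of linear functionals, a
voxel mixing two tissues lands exactly on the chord between the two
pure-tissue phasors, at the intensity-weighted position — which turns
partial-volume unmixing into geometry. The *full-harmonics* projection
chooses three anchor lifetimes (the two tissue T1s and one in between),
takes the plane through their phasor vectors, and projects every voxel onto
it; the resulting 2D coordinates are called **Axis1**/**Axis2**, calibrated
here so the zero-lifetime phasor maps to (1, 0) and the infinite-lifetime
phasor to (0, 0).

Inversion-recovery data rise rather than decay, so each series is first
converted per voxel by sign inversion and asymptote subtraction,
`D_k = S_last − S_k`, using the longest-TI sample as the asymptote estimate.

## Worked example

```python
import numpy as np
from t1phasor import (PhantomSpec, simulate_phantom, ir_to_decay,
                      build_projection_plane, phasor_cloud, axis1_image,
                      build_fraction_library, estimate_volume_fraction)

spec = PhantomSpec()                       # 1000×1000 → 21×21 ring phantom,
                                           # T1 = 1.5 s (myocardium) / 2.0 s (blood)
fractions, stack = simulate_phantom(spec)  # inversion-recovery series at 8 TIs
decays = ir_to_decay(stack)                # sign inversion + asymptote subtraction
plane = build_projection_plane(stack.times, (1.5, 1.75, 2.0),
                               mode="inversion_recovery")
cloud = phasor_cloud(decays, fractions.support, plane)
img = axis1_image(cloud)

print("pure myocardium Axis1:", np.nanmean(img[fractions.f_myo == 1]))
print("pure blood Axis1:     ", np.nanmean(img[fractions.f_blood == 1]))

lib = build_fraction_library(1.5, 2.0, stack.times, plane, step=0.001)
f_hat, dist = estimate_volume_fraction(cloud, lib)
truth = fractions.f_myo / np.clip(fractions.f_myo + fractions.f_blood, 1e-12, None)
print("max fraction error:   ", np.abs(f_hat - truth.ravel()[cloud.voxel_ids]).max())
```

prints

```
pure myocardium Axis1: 0.3550188005791904
pure blood Axis1:      0.29002633260838173
max fraction error:    0.0004895833333333332
```

The two pure-tissue clusters are single points (noiseless phantom); every
mixed voxel lies on the chord between them, and nearest-neighbor lookup in a
0.001-step library recovers each voxel's myocardium signal fraction to
better than the library step. Note that Axis1 values are specific to the
calibration convention of the projection frame (see `docs/methods.md`);
only ratios and orderings are comparable across conventions.

The same pipeline is exposed as a CLI:

```
t1phasor simulate --out sim/
t1phasor phasor --series sim/phantom.nii --ti-sidecar sim/phantom.json \
    --roi sim/roi_support.nii --anchors 1.5 1.75 2.0 \
    --mode inversion_recovery --out out/
t1phasor motion-qc --series-clean sim/phantom.nii --ti-sidecar sim/phantom.json \
    --simulate-shift 8 --roi sim/roi_support.nii --anchors 1.5 1.75 2.0 --out qc/
```

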