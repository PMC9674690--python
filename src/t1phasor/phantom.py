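"""Virtual left-ventricle phantom: partial-volume fractions, simulated
inversion-recovery series, and the motion-corruption transform.

The phantom is a short-axis caricature of the left ventricle: an outer ring
of myocardium around an inner blood disk, rasterized on a fine grid (default
1000 x 1000) and block-averaged down to a coarse acquisition grid (default
21 x 21) so that voxels straddling a boundary acquire genuine partial-volume
area fractions.  The downsampling ratio is deliberately non-integer; each
fine cell is assigned to the coarse voxel containing its center, which
conserves fine-cell counts exactly.

Every coarse voxel's signal is the area-fraction-weighted sum of the two
tissue recoveries (equilibrium signal density 1 per unit volume for both
tissues); voxels fully outside the phantom carry zero signal.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .t1 import ContrastStack

__all__ = [
    "MOLLI_TIMES",
    "PhantomSpec",
    "FractionMap",
    "generate_fraction_map",
    "simulate_stack",
    "simulate_phantom",
    "apply_motion_shift",
    "broaden_roi",
]

#: MOLLI 5(3s)3 inversion times (seconds) used throughout the phantom study.
MOLLI_TIMES = np.array([0.129, 0.209, 1.344, 1.394, 2.494, 2.551, 3.644, 4.807])


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, tissue T1s, sampling and noise of the virtual phantom.

    Radii are fractions of the field of view side (the grid spans a unit
    square, so the largest inscribed radius is 0.5).  Defaults: a ring of
    myocardium (T1 = 1.5 s) around the blood pool (T1 = 2.0 s), noise off.
    """

    fine_grid: int = 1000
    coarse_grid: int = 21
    outer_radius: float = 0.45
    inner_radius: float = 0.30
    t1_myocardium: float = 1.5
    t1_blood: float = 2.0
    times: np.ndarray = field(default_factory=lambda: MOLLI_TIMES.copy())
    density: float = 1.0
    noise_sigma: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        if not 0 < self.inner_radius < self.outer_radius <= 0.5:
            raise ValueError("need 0 < inner_radius < outer_radius <= 0.5")
        if self.t1_myocardium <= 0 or self.t1_blood <= 0:
            raise ValueError("tissue T1 values must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")
        if self.coarse_grid > self.fine_grid:
            raise ValueError("coarse grid cannot exceed the fine grid")


@dataclass(frozen=True)
class FractionMap:
    """Per-coarse-voxel area fractions of myocardium, blood and background."""

    f_myo: np.ndarray
    f_blood: np.ndarray
    f_background: np.ndarray

    def __post_init__(self):
        s = self.f_myo + self.f_blood + self.f_background
        if not np.allclose(s, 1.0, atol=1e-12):
            raise ValueError("fractions must sum to 1 per voxel")

    @property
    def support(self) -> np.ndarray:
        """Mask of voxels carrying any phantom signal."""
        return (self.f_myo + self.f_blood) > 0


def generate_fraction_map(spec: PhantomSpec) -> FractionMap:
    """Rasterize the ring/disk geometry and block-average to the coarse grid."""
    n, m = spec.fine_grid, spec.coarse_grid
    centers = (np.arange(n) + 0.5) / n
    x, y = np.meshgrid(centers, centers, indexing="ij")
    r = np.hypot(x - 0.5, y - 0.5)
    blood = r <= spec.inner_radius
    myo = (r <= spec.outer_radius) & ~blood

    # coarse voxel containing each fine-cell center (non-integer ratio safe)
    idx = np.minimum((np.arange(n) * m) // n, m - 1).astype(int)
    ci = idx[:, None] * m + idx[None, :]

    counts = np.bincount(ci.ravel(), minlength=m * m).reshape(m, m)
    n_myo = np.bincount(ci.ravel(), weights=myo.ravel(), minlength=m * m).reshape(m, m)
    n_blood = np.bincount(ci.ravel(), weights=blood.ravel(), minlength=m * m).reshape(m, m)
    f_myo = n_myo / counts
    f_blood = n_blood / counts
    return FractionMap(f_myo=f_myo, f_blood=f_blood, f_background=1.0 - f_myo - f_blood)


def simulate_stack(
    fractions: FractionMap,
    spec: PhantomSpec,
    mode: str = "inversion_recovery",
) -> ContrastStack:
    """Simulate the (bi-)exponential contrast series for every coarse voxel.

    ``inversion_recovery`` (default): S(t) = density * sum_i f_i (1 - 2 exp(-t/T1_i)),
    to be passed through the standard offset correction before phasor
    processing.  ``decay``: S(t) = density * sum_i f_i exp(-t/T1_i), already in
    decay form.  Gaussian noise of std ``noise_sigma`` is added when enabled;
    with the same seed the output is reproducible sample-for-sample.
    """
    t = spec.times
    if mode == "inversion_recovery":
        k_myo = 1.0 - 2.0 * np.exp(-t / spec.t1_myocardium)
        k_blood = 1.0 - 2.0 * np.exp(-t / spec.t1_blood)
    elif mode == "decay":
        k_myo = np.exp(-t / spec.t1_myocardium)
        k_blood = np.exp(-t / spec.t1_blood)
    else:
        raise ValueError(f"mode must be 'decay' or 'inversion_recovery', got {mode!r}")
    data = spec.density * (
        fractions.f_myo[:, :, None] * k_myo[None, None, :]
        + fractions.f_blood[:, :, None] * k_blood[None, None, :]
    )
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        data = data + rng.normal(0.0, spec.noise_sigma, size=data.shape)
    return ContrastStack(data=data, times=t, converted=(mode == "decay"))


def simulate_phantom(spec: PhantomSpec, mode: str = "inversion_recovery"):
    """Convenience: fraction map plus simulated stack in one call."""
    fractions = generate_fraction_map(spec)
    return fractions, simulate_stack(fractions, spec, mode=mode)


def apply_motion_shift(
    stack: ContrastStack,
    shift_voxels: int,
    axis: str = "vertical",
    frames: str | list[int] = "even",
) -> ContrastStack:
    """Translate selected frames to mimic abrupt inter-frame motion.

    ``frames="even"`` shifts frames 2, 4, 6, ... in 1-based TI-sorted order;
    an explicit list of 0-based frame indices may be given instead.  Vacated
    voxels are zero-filled; a positive shift moves content toward higher
    row (vertical) or column (horizontal) indices.
    """
    shift = int(shift_voxels)
    if axis not in ("vertical", "horizontal"):
        raise ValueError(f"axis must be 'vertical' or 'horizontal', got {axis!r}")
    extent = stack.data.shape[0] if axis == "vertical" else stack.data.shape[1]
    if abs(shift) >= extent:
        raise ValueError(f"|shift| = {abs(shift)} must be smaller than the extent {extent}")
    if frames == "even":
        sel = list(range(1, stack.n_frames, 2))  # 1-based even = 0-based odd
    else:
        sel = sorted(int(i) for i in frames)
        if sel and (sel[0] < 0 or sel[-1] >= stack.n_frames):
            raise ValueError("frame index out of range")
    data = stack.data.copy()
    if shift != 0:
        for i in sel:
            frame = np.zeros_like(data[:, :, i])
            if axis == "vertical":
                if shift > 0:
                    frame[shift:, :] = stack.data[:-shift, :, i]
                else:
                    frame[:shift, :] = stack.data[-shift:, :, i]
            else:
                if shift > 0:
                    frame[:, shift:] = stack.data[:, :-shift, i]
                else:
                    frame[:, :shift] = stack.data[:, -shift:, i]
            data[:, :, i] = frame
    return replace(stack, data=data)


def broaden_roi(mask: np.ndarray, pixels: int) -> np.ndarray:
    """Symmetric morphological broadening of a binary ROI.

    Dilation with a (2*pixels+1) square structuring element, clipped at the
    image borders; the result is always a superset of the input.
    """
    if pixels < 0:
        raise ValueError("pixels must be non-negative")
    mask = np.asarray(mask, dtype=bool)
    if pixels == 0:
        return mask.copy()
    footprint = np.ones((2 * pixels + 1, 2 * pixels + 1), dtype=bool)
    return ndimage.binary_dilation(mask, structure=footprint)
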