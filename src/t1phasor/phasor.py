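"""Full-harmonics phasor transform and its 2D projection.

A voxel's signal decay sampled at M contrast points is mapped, without any
fitting, to the normalized discrete Fourier coefficients

    G_n = sum_k v_k cos(2 pi n k / M) / sum_k v_k
    S_n = sum_k v_k sin(2 pi n k / M) / sum_k v_k,      n = 1 .. floor(M/2)

taken over the sample *index* k (the sampling grid may be non-uniform in
physical time; data and reference curves share the identical convention, so
the reference locus is sampling-dependent by construction).  Stacking all
harmonics gives a point in 2N-dimensional phasor space.  Because the map
decay -> (G, S) is a ratio of linear functionals, the phasor of a sum of
decays is the total-intensity-weighted convex combination of the component
phasors — the property that makes partial-volume voxels fall on the chord
between the two pure-tissue positions.

The 2D view ("Axis1"/"Axis2") is an orthogonal projection onto the plane
through the phasor vectors of three chosen anchor lifetimes, followed by a
similarity calibration that pins the zero-lifetime phasor (all (1, 0)) to
(1, 0) and the infinite-lifetime phasor (the zero vector) to (0, 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegeneratePlaneError, DegenerateVoxelError, DimensionError

__all__ = [
    "PhasorVector",
    "ReferenceCurve",
    "ProjectionPlane",
    "PhasorCloud",
    "dft_phasor",
    "mono_exponential_phasor",
    "mono_exponential_decay",
    "build_reference_curve",
    "build_projection_plane",
    "project",
    "phasor_cloud",
]

#: Rank tolerance below which three anchor phasors are treated as collinear.
RANK_TOL = 1e-10


def _check_times(times: np.ndarray) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size < 3:
        raise ValueError("need a 1D grid of at least 3 contrast times")
    if np.any(np.diff(times) <= 0):
        raise ValueError("contrast times must be strictly increasing")
    return times


@dataclass(frozen=True)
class PhasorVector:
    """Normalized Fourier coefficients of one decay.

    Attributes
    ----------
    g, s : ndarray, shape (N,)
        Cosine and sine coefficients per harmonic, n = 1..N = floor(M/2).
    total : float
        Zeroth-order coefficient (sum of the decay samples); the equilibrium
        signal that the harmonics are normalized by.
    """

    g: np.ndarray
    s: np.ndarray
    total: float

    @property
    def n_harmonics(self) -> int:
        return self.g.size

    @property
    def vector(self) -> np.ndarray:
        """The stacked 2N-dimensional real coordinate (all G_n then all S_n)."""
        return np.concatenate([self.g, self.s])


def _dft_matrix(m: int) -> tuple[np.ndarray, np.ndarray]:
    """Cosine/sine kernels, shape (N, M), for an index-based DFT."""
    n_harm = m // 2
    n = np.arange(1, n_harm + 1)[:, None]
    k = np.arange(m)[None, :]
    phase = 2.0 * np.pi * n * k / m
    return np.cos(phase), np.sin(phase)


def dft_phasor(values: np.ndarray) -> PhasorVector:
    """Phasor transform of a single decay.

    Raises
    ------
    DegenerateVoxelError
        If the decay sums to a non-positive total (no normalization exists).
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or v.size < 3:
        raise ValueError("decay must be a 1D vector of at least 3 samples")
    total = float(v.sum())
    if total <= 0.0:
        raise DegenerateVoxelError(f"decay total {total!r} is not positive")
    cos_k, sin_k = _dft_matrix(v.size)
    return PhasorVector(g=(cos_k @ v) / total, s=(sin_k @ v) / total, total=total)


def dft_phasor_many(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized phasor transform for a (n_voxels, M) decay array.

    Returns the (n_voxels, 2N) stacked coordinates and the (n_voxels,)
    totals.  Degenerate rows (total <= 0) come back as NaN coordinates; the
    caller decides how to report them.
    """
    v = np.asarray(values, dtype=float)
    if v.ndim != 2 or v.shape[1] < 3:
        raise ValueError("expected a (n_voxels, M>=3) decay array")
    totals = v.sum(axis=1)
    cos_k, sin_k = _dft_matrix(v.shape[1])
    with np.errstate(divide="ignore", invalid="ignore"):
        coords = np.concatenate([v @ cos_k.T, v @ sin_k.T], axis=1) / totals[:, None]
    coords[totals <= 0] = np.nan
    return coords, totals


def mono_exponential_decay(lifetime: float, times: np.ndarray, mode: str) -> np.ndarray:
    """Sampled mono-exponential decay for reference construction.

    ``mode="decay"`` samples exp(-t/tau) directly; ``mode="inversion_recovery"``
    samples the recovery 1 - 2 exp(-t/tau) and converts it like measured data
    (sign inversion plus last-sample asymptote subtraction).  Both are
    evaluated in the rescaled form exp(-(t_k - t_0)/tau), exactly proportional
    to the unscaled decay (the phasor is scale-invariant) but immune to
    underflow at extreme lifetimes.
    """
    times = _check_times(times)
    if lifetime <= 0:
        raise ValueError(f"lifetime must be positive, got {lifetime!r}")
    e = np.exp(-(times - times[0]) / lifetime)
    if mode == "decay":
        return e
    if mode == "inversion_recovery":
        # converted IR decay: S_last - S_k = 2(exp(-t_k/tau) - exp(-t_max/tau))
        return e - e[-1]
    raise ValueError(f"mode must be 'decay' or 'inversion_recovery', got {mode!r}")


def mono_exponential_phasor(lifetime: float, times: np.ndarray, mode: str = "decay") -> PhasorVector:
    """Phasor of a pure mono-exponential decay at the given lifetime."""
    d = mono_exponential_decay(lifetime, times, mode)
    if d.sum() <= 0.0:
        # only reachable through numerically degenerate IR limits
        raise DegenerateVoxelError(
            f"mono-exponential reference at lifetime {lifetime!r} is degenerate"
        )
    return dft_phasor(d)


@dataclass(frozen=True)
class ProjectionPlane:
    """Affine 2D view of the 2N-dimensional phasor space.

    The plane passes through the phasor vectors of three anchor lifetimes;
    ``basis_u1``/``basis_u2`` are an orthonormal in-plane basis (Gram-Schmidt
    on the anchor differences) with ``origin`` the middle anchor's phasor.
    ``calib_matrix``/``calib_offset`` hold the 2D similarity (with reflection
    resolved so anchors have Axis2 >= 0) that pins the zero-lifetime phasor
    to (1, 0) and the infinite-lifetime phasor to (0, 0).
    """

    anchor_lifetimes: tuple[float, float, float]
    times: np.ndarray
    mode: str
    origin: np.ndarray
    basis_u1: np.ndarray
    basis_u2: np.ndarray
    calib_matrix: np.ndarray
    calib_offset: np.ndarray

    @property
    def n_harmonics(self) -> int:
        return self.basis_u1.size // 2

    def raw_coords(self, stacked: np.ndarray) -> np.ndarray:
        """In-plane coordinates (before calibration) of (..., 2N) vectors."""
        d = np.asarray(stacked, dtype=float) - self.origin
        return np.stack([d @ self.basis_u1, d @ self.basis_u2], axis=-1)

    def apply(self, stacked: np.ndarray) -> np.ndarray:
        """Calibrated (Axis1, Axis2) of (..., 2N) stacked phasor vectors."""
        p = self.raw_coords(stacked)
        return p @ self.calib_matrix.T + self.calib_offset


def build_projection_plane(
    times: np.ndarray,
    anchors: tuple[float, float, float],
    mode: str = "inversion_recovery",
) -> ProjectionPlane:
    """Construct the full-harmonics projection plane from three lifetimes.

    The anchors are typically the two tissue T1 values plus an in-between
    value, chosen to spread the bi-exponential chord away from the
    mono-exponential reference locus.

    Raises
    ------
    DegeneratePlaneError
        If the anchor phasor vectors are collinear (e.g. duplicated
        lifetimes) within rank tolerance.
    """
    times = _check_times(times)
    anchors = tuple(float(a) for a in anchors)
    if len(anchors) != 3:
        raise ValueError("exactly three anchor lifetimes are required")
    if len(set(anchors)) != 3:
        raise DegeneratePlaneError(f"anchor lifetimes must be pairwise distinct: {anchors}")
    va, vb, vc = (mono_exponential_phasor(a, times, mode).vector for a in anchors)

    d1 = va - vb
    d2 = vc - vb
    n1 = np.linalg.norm(d1)
    if n1 < RANK_TOL:
        raise DegeneratePlaneError("first anchor difference is numerically zero")
    u1 = d1 / n1
    r = d2 - (d2 @ u1) * u1
    n2 = np.linalg.norm(r)
    if n2 < RANK_TOL * max(1.0, np.linalg.norm(d2)):
        raise DegeneratePlaneError("anchor phasor vectors are collinear; no plane")
    u2 = r / n2

    # Exact lifetime-limit phasors: tau->0 is a delta at the first sample
    # (all G_n = 1, S_n = 0); tau->inf is the zero vector.
    n_harm = va.size // 2
    v_zero_life = np.concatenate([np.ones(n_harm), np.zeros(n_harm)])
    v_inf_life = np.zeros(2 * n_harm)

    def _raw(vec: np.ndarray) -> np.ndarray:
        d = vec - vb
        return np.array([d @ u1, d @ u2])

    p_inf = _raw(v_inf_life)
    p_zero = _raw(v_zero_life)

    for reflect in (False, True):
        ref = np.diag([1.0, -1.0]) if reflect else np.eye(2)
        z0 = complex(*(ref @ p_inf))
        z1 = complex(*(ref @ p_zero))
        a = 1.0 / (z1 - z0)  # rotation+scale mapping z0 -> 0, z1 -> 1
        rot = np.array([[a.real, -a.imag], [a.imag, a.real]])
        matrix = rot @ ref
        offset = -matrix @ p_inf
        axis2 = np.array([matrix @ _raw(v) + offset for v in (va, vb, vc)])[:, 1]
        if axis2.sum() >= 0.0:
            break

    return ProjectionPlane(
        anchor_lifetimes=anchors,
        times=times,
        mode=mode,
        origin=vb,
        basis_u1=u1,
        basis_u2=u2,
        calib_matrix=matrix,
        calib_offset=offset,
    )


def project(vector: PhasorVector | np.ndarray, plane: ProjectionPlane) -> np.ndarray:
    """(Axis1, Axis2) of one phasor vector (or a (..., 2N) array of them)."""
    stacked = vector.vector if isinstance(vector, PhasorVector) else np.asarray(vector, float)
    if stacked.shape[-1] != 2 * plane.n_harmonics:
        raise DimensionError(
            f"vector has {stacked.shape[-1]} components, plane expects {2 * plane.n_harmonics}"
        )
    return plane.apply(stacked)


@dataclass(frozen=True)
class ReferenceCurve:
    """Mono-exponential locus ("semicircle") in phasor space.

    Built with the identical sampling grid and decay convention as the data,
    so voxels with truly single-exponential decays fall exactly on it.
    """

    lifetimes: np.ndarray
    vectors: np.ndarray  # (n_lifetimes, 2N) stacked phasor coordinates
    projected: np.ndarray | None = None  # (n_lifetimes, 2) after calibration


def default_lifetime_grid(anchors: tuple[float, float, float], n: int = 200) -> np.ndarray:
    """Log-spaced lifetime grid spanning 0.05x to 20x the anchor range."""
    lo, hi = min(anchors), max(anchors)
    return np.logspace(np.log10(0.05 * lo), np.log10(20.0 * hi), n)


def build_reference_curve(
    times: np.ndarray,
    lifetime_grid: np.ndarray | None = None,
    mode: str = "decay",
    plane: ProjectionPlane | None = None,
) -> ReferenceCurve:
    """Evaluate the mono-exponential reference locus on a lifetime grid."""
    times = _check_times(times)
    if lifetime_grid is None:
        if plane is None:
            raise ValueError("need either an explicit lifetime grid or a plane with anchors")
        lifetime_grid = default_lifetime_grid(plane.anchor_lifetimes)
    grid = np.asarray(lifetime_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("lifetime grid is empty")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("lifetime grid must be positive and strictly increasing")
    vectors = np.array([mono_exponential_phasor(t, times, mode).vector for t in grid])
    projected = plane.apply(vectors) if plane is not None else None
    return ReferenceCurve(lifetimes=grid, vectors=vectors, projected=projected)


@dataclass(frozen=True)
class PhasorCloud:
    """Calibrated (Axis1, Axis2) coordinates for every valid ROI voxel.

    ``voxel_ids`` are row-major linear indices into the image grid.  Voxels
    whose decay total is non-positive cannot be normalized; they are excluded
    from the cloud but their ids are kept in ``degenerate_ids`` so callers
    can report them.
    """

    voxel_ids: np.ndarray
    axis1: np.ndarray
    axis2: np.ndarray
    grid_shape: tuple[int, int]
    degenerate_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def __len__(self) -> int:
        return self.voxel_ids.size

    @property
    def points(self) -> np.ndarray:
        return np.stack([self.axis1, self.axis2], axis=1)


def phasor_cloud(stack, roi: np.ndarray, plane: ProjectionPlane) -> PhasorCloud:
    """Per-voxel phasor projection of a converted contrast series.

    Parameters
    ----------
    stack : ContrastStack
        Must already be in decay form (``converted`` flag set).
    roi : bool ndarray, shape (rows, cols)
        Mask of voxels to include; must be non-empty.
    plane : ProjectionPlane
        Built from the same contrast grid as the stack.
    """
    from .t1 import ContrastStack  # local import to avoid a cycle

    if not isinstance(stack, ContrastStack):
        raise TypeError("stack must be a ContrastStack")
    if not stack.converted:
        raise DimensionError(
            "stack is still in inversion-recovery form; apply ir_to_decay first"
        )
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.data.shape[:2]:
        raise ValueError(f"ROI shape {roi.shape} does not match grid {stack.data.shape[:2]}")
    if not roi.any():
        raise ValueError("ROI is empty")
    if stack.times.size != plane.times.size or not np.allclose(stack.times, plane.times):
        raise DimensionError("stack and plane were built from different contrast grids")

    ids = np.flatnonzero(roi.ravel())
    decays = stack.data.reshape(-1, stack.data.shape[2])[ids]
    coords, totals = dft_phasor_many(decays)
    ok = totals > 0
    proj = plane.apply(coords[ok])
    return PhasorCloud(
        voxel_ids=ids[ok],
        axis1=proj[:, 0],
        axis2=proj[:, 1],
        grid_shape=stack.data.shape[:2],
        degenerate_ids=ids[~ok],
    )
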