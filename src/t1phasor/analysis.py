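"""From phasor clouds to images, segmentations, volume fractions and a
motion-scatter index.

Partial-volume unmixing exploits the exact chord geometry of the phasor
transform: a voxel mixing two tissues with signal fractions f and 1-f
projects onto the chord between the two pure-tissue positions, at the
intensity-weighted (not volume-weighted) position.  A pre-computed library
of chord positions for a dense fraction grid turns the inverse problem into
a nearest-neighbor lookup.

Motion corruption shows up as scatter of the cloud perpendicular to the
mono-exponential reference locus; the index here is the standard deviation
of the signed point-to-polyline distance, compared between a test and a
reference acquisition as a ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .phasor import PhasorCloud, ProjectionPlane, ReferenceCurve, dft_phasor, project

__all__ = [
    "FractionLibrary",
    "SegmentationIntervals",
    "SegmentationMap",
    "LABEL_CODES",
    "build_fraction_library",
    "estimate_volume_fraction",
    "axis1_image",
    "axis2_image",
    "segment_axis1",
    "motion_scatter_index",
    "scatter_ratio",
]

#: Integer codes used in segmentation label images.
LABEL_CODES = {"other": 0, "myocardium": 1, "partial_volume": 2, "blood": 3}


@dataclass(frozen=True)
class FractionLibrary:
    """Chord positions for all volume fractions of a two-tissue mixture.

    ``fractions[i]`` is the myocardium *signal* fraction S_myo/S_tot at
    equilibrium; ``coords[i]`` its projected (Axis1, Axis2).  Endpoints are
    the pure-component projections.
    """

    fractions: np.ndarray
    coords: np.ndarray
    component_lifetimes: tuple[float, float]


def _mixture_decay(f: float, t1_a: float, t1_b: float, times: np.ndarray, mode: str) -> np.ndarray:
    """Converted decay of an f : (1-f) mixture, unit equilibrium density."""
    if mode == "inversion_recovery":
        s = f * (1 - 2 * np.exp(-times / t1_a)) + (1 - f) * (1 - 2 * np.exp(-times / t1_b))
        return s[-1] - s
    if mode == "decay":
        return f * np.exp(-times / t1_a) + (1 - f) * np.exp(-times / t1_b)
    raise ValueError(f"unknown mode {mode!r}")


def build_fraction_library(
    t1_a: float,
    t1_b: float,
    times: np.ndarray,
    plane: ProjectionPlane,
    step: float = 0.001,
) -> FractionLibrary:
    """Tabulate projected positions of mixtures over a fraction grid.

    ``t1_a`` is the lifetime whose fraction is tabulated (myocardium by
    convention), ``t1_b`` the complement (blood).  Mixtures follow the same
    simulation mode and offset conversion as the data so library and cloud
    live in the same frame.
    """
    if t1_a <= 0 or t1_b <= 0 or t1_a == t1_b:
        raise ConfigurationError("component lifetimes must be positive and distinct")
    if not 0 < step <= 0.01:
        raise ConfigurationError("fraction step must be in (0, 0.01]")
    times = np.asarray(times, dtype=float)
    n = int(round(1.0 / step))
    fractions = np.linspace(0.0, 1.0, n + 1)
    decays = np.array([_mixture_decay(f, t1_a, t1_b, times, plane.mode) for f in fractions])
    coords = np.array([project(dft_phasor(d), plane) for d in decays])
    return FractionLibrary(
        fractions=fractions, coords=coords, component_lifetimes=(t1_a, t1_b)
    )


def estimate_volume_fraction(
    cloud: PhasorCloud, library: FractionLibrary
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest-library-entry fraction per cloud point.

    Returns ``(fractions, distances)``; the distance of each point to its
    matched library entry is reported for quality control (large values mean
    the point is far off the two-component chord).  Ties break toward the
    smaller fraction.
    """
    if len(cloud) == 0 or library.fractions.size == 0:
        raise ValueError("cloud and library must be non-empty")
    pts = cloud.points  # (n, 2)
    d2 = ((pts[:, None, :] - library.coords[None, :, :]) ** 2).sum(axis=2)
    # argmin returns the first minimum; fractions ascend, so ties go to smaller f
    idx = np.argmin(d2, axis=1)
    return library.fractions[idx], np.sqrt(d2[np.arange(len(pts)), idx])


def _scatter_image(cloud: PhasorCloud, values: np.ndarray) -> np.ndarray:
    ids = cloud.voxel_ids
    if np.unique(ids).size != ids.size:
        raise ValueError("duplicate voxel ids in cloud")
    img = np.full(cloud.grid_shape[0] * cloud.grid_shape[1], np.nan)
    img[ids] = values
    return img.reshape(cloud.grid_shape)


def axis1_image(cloud: PhasorCloud, invert: bool = False) -> np.ndarray:
    """Scatter the Axis1 coordinate back onto the image grid (NaN elsewhere).

    ``invert`` flips the value scale (max+min minus value) so the colormap
    ordering matches that of a conventional T1 map.
    """
    vals = cloud.axis1
    if invert and vals.size:
        vals = (np.nanmax(vals) + np.nanmin(vals)) - vals
    return _scatter_image(cloud, vals)


def axis2_image(cloud: PhasorCloud) -> np.ndarray:
    """Scatter the Axis2 coordinate back onto the image grid."""
    return _scatter_image(cloud, cloud.axis2)


@dataclass(frozen=True)
class SegmentationIntervals:
    """Half-open Axis1 intervals (lo, hi] per tissue class.

    The printed notation "a > Axis1 > b" is implemented as b < Axis1 <= a;
    exact-boundary voxels (measure zero for real data) go to the lower
    interval's class.  Intervals must be pairwise disjoint.
    """

    intervals: dict[str, tuple[float, float]]

    def __post_init__(self):
        items = list(self.intervals.items())
        for name, (lo, hi) in items:
            if not lo < hi:
                raise ConfigurationError(f"interval {name!r}: need lower < upper")
        for i, (na, (la, ha)) in enumerate(items):
            for nb, (lb, hb) in items[i + 1:]:
                if max(la, lb) < min(ha, hb):
                    raise ConfigurationError(f"intervals {na!r} and {nb!r} overlap")

    def classify(self, axis1: np.ndarray) -> np.ndarray:
        """Integer label per value (LABEL_CODES; 'other' outside all intervals)."""
        labels = np.full(np.shape(axis1), LABEL_CODES["other"], dtype=int)
        for name, (lo, hi) in self.intervals.items():
            code = LABEL_CODES.get(name)
            if code is None:
                raise ConfigurationError(f"unknown class {name!r}")
            inside = (np.asarray(axis1) > lo) & (np.asarray(axis1) <= hi)
            labels[inside] = code
        return labels


#: Axis1 intervals printed for the phantom study (dataset-specific config).
SIMULATION_INTERVALS = SegmentationIntervals(
    {"myocardium": (0.85, 0.88), "partial_volume": (0.43, 0.85), "blood": (0.41, 0.43)}
)

#: Axis1 intervals used for the two patient datasets (myocardium / scar /
#: blood; "scar" occupies the partial_volume slot of the label scheme).
PATIENT_INTERVALS = (
    SegmentationIntervals(
        {"myocardium": (0.56, 0.65), "partial_volume": (0.44, 0.56), "blood": (0.35, 0.44)}
    ),
    SegmentationIntervals(
        {"myocardium": (0.62, 0.74), "partial_volume": (0.54, 0.62), "blood": (0.40, 0.54)}
    ),
)


@dataclass(frozen=True)
class SegmentationMap:
    """Per-voxel class labels (see LABEL_CODES)."""

    labels: np.ndarray

    def mask(self, name: str) -> np.ndarray:
        return self.labels == LABEL_CODES[name]


def segment_axis1(axis1_img: np.ndarray, intervals: SegmentationIntervals) -> SegmentationMap:
    """Classify an Axis1 image by interval membership (NaN -> other)."""
    img = np.asarray(axis1_img, dtype=float)
    labels = intervals.classify(np.nan_to_num(img, nan=np.inf))
    labels[~np.isfinite(img)] = LABEL_CODES["other"]
    return SegmentationMap(labels=labels)


def _signed_polyline_distance(points: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Signed minimal distance of each point to a polyline.

    The magnitude is the true minimal distance over all segments; the sign is
    taken from the side (cross-product sign) of the nearest segment.
    """
    p = points[:, None, :]  # (n, 1, 2)
    a = poly[None, :-1, :]  # (1, m-1, 2)
    b = poly[None, 1:, :]
    ab = b - a
    denom = (ab ** 2).sum(axis=2)
    denom = np.where(denom == 0, 1.0, denom)
    t = np.clip(((p - a) * ab).sum(axis=2) / denom, 0.0, 1.0)
    foot = a + t[:, :, None] * ab
    d2 = ((p - foot) ** 2).sum(axis=2)  # (n, m-1)
    nearest = np.argmin(d2, axis=1)
    rows = np.arange(points.shape[0])
    cross = ab[0, nearest, 0] * (points[:, 1] - a[0, nearest, 1]) - ab[0, nearest, 1] * (
        points[:, 0] - a[0, nearest, 0]
    )
    return np.sign(cross) * np.sqrt(d2[rows, nearest])


def motion_scatter_index(
    cloud: PhasorCloud, reference: ReferenceCurve, statistic: str = "std"
) -> float:
    """Spread of the cloud perpendicular to the projected reference curve.

    ``statistic="std"`` (default) is the standard deviation of the signed
    point-to-polyline distances; ``"mad"`` the median absolute deviation
    from their median.  Motion corruption inflates this index relative to a
    clean acquisition of the same anatomy.
    """
    if reference.projected is None:
        raise ValueError("reference curve must be projected (build it with a plane)")
    poly = np.asarray(reference.projected, dtype=float)
    if poly.shape[0] < 2:
        raise ValueError("reference polyline needs at least 2 points")
    if len(cloud) < 10:
        raise ValueError("need at least 10 cloud points for a scatter estimate")
    d = _signed_polyline_distance(cloud.points, poly)
    if statistic == "std":
        return float(np.std(d, ddof=1))
    if statistic == "mad":
        return float(np.median(np.abs(d - np.median(d))))
    raise ValueError(f"unknown statistic {statistic!r}")


def scatter_ratio(
    test: PhasorCloud, clean: PhasorCloud, reference: ReferenceCurve, statistic: str = "std"
) -> float:
    """motion_scatter_index(test) / motion_scatter_index(clean)."""
    return motion_scatter_index(test, reference, statistic) / motion_scatter_index(
        clean, reference, statistic
    )
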