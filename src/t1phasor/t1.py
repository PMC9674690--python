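"""Inversion-recovery series handling and the comparison mono-exponential fit.

An inversion-recovery T1 series samples S(TI) = A - 2 A exp(-TI/T1), an
*increasing* curve, while the phasor transform expects a decay.  The
conversion inverts the sign and subtracts the asymptote, approximated by the
longest-TI sample (in MOLLI the last TI is several times the expected T1):

    D_k = S_last - S_k

so D is decreasing, D_last = 0, and for a pure tissue D is exactly
proportional to exp(-TI/T1) minus a constant.  The terminal zero sample is
retained, keeping the sample count — and hence the harmonic grid — identical
for data and reference curves.

The two-parameter fit v ~ B exp(-t/T1) is the conventional per-voxel
baseline the phasor maps are compared against; note that on *converted* IR
data the model class is wrong by a constant, which is precisely the kind of
model bias the phasor approach avoids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import least_squares

from .errors import StateError

__all__ = ["ContrastStack", "T1Map", "ir_to_decay", "restore_polarity", "fit_monoexp", "t1_map"]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContrastStack:
    """A rows x cols x frames signal series with its contrast times.

    ``times`` are inversion times in seconds, strictly increasing;
    ``converted`` records whether the IR->decay conversion has been applied.
    """

    data: np.ndarray
    times: np.ndarray
    converted: bool = False

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times, dtype=float)
        if data.ndim != 3:
            raise ValueError(f"data must be rows x cols x frames, got shape {data.shape}")
        if data.shape[2] < 3:
            raise ValueError("need at least 3 frames")
        if times.shape != (data.shape[2],):
            raise ValueError("one contrast time per frame is required")
        order = np.argsort(times)
        data = data[:, :, order]
        times = times[order]
        if np.any(np.diff(times) <= 0):
            raise ValueError("contrast times must be distinct")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.data.shape[:2]

    @property
    def n_frames(self) -> int:
        return self.data.shape[2]


def restore_polarity(stack: ContrastStack) -> ContrastStack:
    """Optional magnitude-data polarity restoration.

    Magnitude-only IR images lose the sign of the early-TI samples; this flips
    the sign of every sample acquired before each voxel's minimum.  Off by
    default in all pipelines: input data are assumed phase-sensitive.
    """
    if stack.converted:
        raise StateError("polarity restoration applies to raw IR data only")
    idx_min = np.argmin(stack.data, axis=2)
    k = np.arange(stack.n_frames)
    flip = k[None, None, :] < idx_min[:, :, None]
    data = np.where(flip, -stack.data, stack.data)
    return replace(stack, data=data)


def ir_to_decay(stack: ContrastStack) -> ContrastStack:
    """Convert an inversion-recovery series to decay form.

    Per voxel: D_k = S_last - S_k (sign inversion plus asymptote
    subtraction with the longest-TI sample as the asymptote estimate).

    Raises
    ------
    StateError
        If the stack is already converted.
    """
    if stack.converted:
        raise StateError("stack has already been converted to decay form")
    decays = stack.data[:, :, -1:] - stack.data
    return ContrastStack(data=decays, times=stack.times, converted=True)


@dataclass(frozen=True)
class T1Map:
    """Per-voxel mono-exponential fit results (NaN where the fit failed)."""

    t1: np.ndarray
    amplitude: np.ndarray
    valid: np.ndarray


def fit_monoexp(times: np.ndarray, values: np.ndarray) -> tuple[float, float]:
    """Two-parameter least-squares fit of v ~ B exp(-t/T1).

    Initialized from a log-linear regression on the positive samples.
    Returns ``(nan, nan)`` instead of raising when the voxel cannot be fit
    (all-zero decay, no positive samples, or optimizer failure), so that map
    construction can simply mark the voxel invalid.
    """
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.size < 3 or v.shape != t.shape:
        raise ValueError("need matching time/value vectors of at least 3 samples")
    pos = v > 0
    if v.sum() <= 0 or pos.sum() < 2:
        return np.nan, np.nan
    # log-linear init: log v = log B - t/T1 on positive samples
    slope, intercept = np.polyfit(t[pos], np.log(v[pos]), 1)
    rate0 = max(-slope, 1e-6)
    b0 = float(np.exp(intercept))

    def resid(p):
        b, rate = p
        return b * np.exp(-rate * t) - v

    try:
        sol = least_squares(
            resid,
            x0=[b0, rate0],
            bounds=([0.0, 1e-9], [np.inf, np.inf]),
            max_nfev=200,
        )
    except Exception:  # pragma: no cover - optimizer hard failure
        return np.nan, np.nan
    if not sol.success or sol.x[1] <= 0:
        return np.nan, np.nan
    b, rate = sol.x
    return 1.0 / rate, b


def t1_map(stack: ContrastStack, roi: np.ndarray) -> T1Map:
    """Voxel-wise two-parameter fit over an ROI of a converted stack."""
    if not stack.converted:
        raise StateError("convert the stack with ir_to_decay before fitting")
    roi = np.asarray(roi, dtype=bool)
    if roi.shape != stack.grid_shape:
        raise ValueError("ROI shape does not match the image grid")
    if not roi.any():
        raise ValueError("ROI is empty")
    t1 = np.full(stack.grid_shape, np.nan)
    amp = np.full(stack.grid_shape, np.nan)
    for r, c in zip(*np.nonzero(roi)):
        t1[r, c], amp[r, c] = fit_monoexp(stack.times, stack.data[r, c])
    valid = np.isfinite(t1)
    n_roi = int(roi.sum())
    log.info(
        "t1_map: %d/%d ROI voxels fit; T1 median %.4g s",
        int(valid.sum()), n_roi, float(np.nanmedian(t1)) if valid.any() else np.nan,
    )
    return T1Map(t1=t1, amplitude=amp, valid=valid)
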