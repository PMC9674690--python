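"""Readers and writers for the formats the tool touches.

Supported series inputs:

* NIfTI volume + JSON sidecar — the volume holds rows x cols x frames, the
  sidecar ``{"inversion_times": [...], "units": "ms"|"s"}``.
* DICOM directory — one file per frame, inversion time taken from the
  ``InversionTime`` attribute (milliseconds per the standard).
* CSV decay table — wide layout with ``row``/``col`` index columns and one
  column per frame, the column name being the contrast time in seconds
  (``repr`` of the float, so a write/read cycle is bit-exact).

Times are stored internally in seconds.  Outputs: 2D maps as NIfTI or TIFF,
clouds/libraries as CSV (0-based, row-major ``voxel_id``), and a JSON
provenance file echoing every parameter of the run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import FormatError
from .phasor import PhasorCloud
from .t1 import ContrastStack

__all__ = [
    "SeriesBundle",
    "read_series",
    "write_series_csv",
    "write_nifti_series",
    "write_map",
    "read_map",
    "write_cloud_csv",
    "read_cloud_csv",
    "write_provenance",
    "plot_phasor",
]


@dataclass(frozen=True)
class SeriesBundle:
    """A contrast stack plus where it came from."""

    stack: ContrastStack
    provenance: dict
    sidecar: dict


def _times_to_seconds(times, units: str) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if units == "ms":
        return times / 1000.0
    if units == "s":
        return times
    raise FormatError(f"sidecar units must be 'ms' or 's', got {units!r}")


def read_series(path: str | Path, format: str, sidecar: str | Path | None = None) -> SeriesBundle:
    """Read a contrast series; frames come back sorted by inversion time."""
    path = Path(path)
    if format == "nifti+json":
        return _read_nifti(path, sidecar)
    if format == "dicom":
        return _read_dicom(path)
    if format == "csv":
        return _read_csv(path)
    raise FormatError(f"unknown series format {format!r}")


def _read_nifti(path: Path, sidecar_path: str | Path | None) -> SeriesBundle:
    if sidecar_path is None:
        sidecar_path = path.with_suffix("").with_suffix("").parent / (
            path.name.split(".")[0] + ".json"
        )
    sidecar_path = Path(sidecar_path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    if "inversion_times" not in sidecar:
        raise FormatError("sidecar lacks an 'inversion_times' key")
    times = _times_to_seconds(sidecar["inversion_times"], sidecar.get("units", "s"))
    data = np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
    if data.ndim != 3:
        raise FormatError(f"expected a 3D volume, got shape {data.shape}")
    if data.shape[2] != times.size:
        raise FormatError(
            f"sidecar lists {times.size} inversion times for {data.shape[2]} frames"
        )
    stack = ContrastStack(data=data, times=times)
    prov = {"format": "nifti+json", "files": [str(path), str(sidecar_path)]}
    return SeriesBundle(stack=stack, provenance=prov, sidecar=sidecar)


def _read_dicom(path: Path) -> SeriesBundle:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.suffix.lower() in (".dcm", ".ima"))
    if not files:
        raise FormatError(f"no DICOM files found under {path}")
    frames, times = [], []
    shape = None
    for f in files:
        ds = pydicom.dcmread(str(f))
        ti = getattr(ds, "InversionTime", None)
        if ti is None:
            raise FormatError(f"DICOM frame {f.name} lacks an InversionTime attribute")
        arr = ds.pixel_array.astype(float)
        if shape is None:
            shape = arr.shape
        elif arr.shape != shape:
            raise FormatError(f"frame {f.name} grid {arr.shape} differs from {shape}")
        frames.append(arr)
        times.append(float(ti) / 1000.0)  # DICOM InversionTime is in ms
    stack = ContrastStack(data=np.stack(frames, axis=2), times=np.array(times))
    prov = {"format": "dicom", "files": [str(f) for f in files]}
    return SeriesBundle(stack=stack, provenance=prov, sidecar={"inversion_times": times, "units": "s"})


def _read_csv(path: Path) -> SeriesBundle:
    df = pd.read_csv(path, float_precision="round_trip")
    if "row" not in df.columns or "col" not in df.columns:
        raise FormatError("CSV decay table needs 'row' and 'col' columns")
    time_cols = [c for c in df.columns if c not in ("row", "col")]
    try:
        times = np.array([float(c) for c in time_cols])
    except ValueError as exc:
        raise FormatError(f"CSV frame columns must be times in seconds: {exc}") from exc
    rows = df["row"].to_numpy(int)
    cols = df["col"].to_numpy(int)
    nr, nc = rows.max() + 1, cols.max() + 1
    if len(df) != nr * nc:
        raise FormatError("CSV decay table must cover the full row x col grid")
    data = np.full((nr, nc, times.size), np.nan)
    data[rows, cols, :] = df[time_cols].to_numpy(float)
    stack = ContrastStack(data=data, times=times)
    prov = {"format": "csv", "files": [str(path)]}
    return SeriesBundle(stack=stack, provenance=prov, sidecar={"inversion_times": times.tolist(), "units": "s"})


def write_series_csv(stack: ContrastStack, path: str | Path) -> Path:
    """Write a stack as the wide CSV decay table (round-trips bit-exactly)."""
    path = Path(path)
    nr, nc, _ = stack.data.shape
    rr, cc = np.meshgrid(np.arange(nr), np.arange(nc), indexing="ij")
    df = pd.DataFrame({"row": rr.ravel(), "col": cc.ravel()})
    for k, t in enumerate(stack.times):
        df[repr(float(t))] = stack.data[:, :, k].ravel()
    # default float formatting is the shortest round-trippable repr
    df.to_csv(path, index=False)
    return path


def write_nifti_series(stack: ContrastStack, path: str | Path, units: str = "s") -> tuple[Path, Path]:
    """Write a stack as NIfTI + JSON sidecar."""
    path = Path(path)
    nib.save(nib.Nifti1Image(stack.data, affine=np.eye(4)), str(path))
    times = stack.times * 1000.0 if units == "ms" else stack.times
    sidecar = path.parent / (path.name.split(".")[0] + ".json")
    sidecar.write_text(
        json.dumps({"inversion_times": times.tolist(), "units": units}, indent=2)
    )
    return path, sidecar


def write_map(image: np.ndarray, path: str | Path) -> Path:
    """Write a 2D map as NIfTI (.nii/.nii.gz) or 32-bit TIFF (.tif)."""
    path = Path(path)
    image = np.asarray(image)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        tifffile.imwrite(str(path), image.astype(np.float32))
    else:
        nib.save(nib.Nifti1Image(image.astype(float), affine=np.eye(4)), str(path))
    return path


def read_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix in (".tif", ".tiff"):
        import tifffile

        return np.asarray(tifffile.imread(str(path)))
    return np.asarray(nib.load(str(path)).get_fdata())


_CLOUD_HEADER = "# voxel_id: 0-based row-major linear index into the image grid\n"


def write_cloud_csv(cloud: PhasorCloud, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"voxel_id": cloud.voxel_ids, "axis1": cloud.axis1, "axis2": cloud.axis2}
    )
    with open(path, "w") as fh:
        fh.write(_CLOUD_HEADER)
        fh.write(f"# grid_shape: {cloud.grid_shape[0]} {cloud.grid_shape[1]}\n")
        df.to_csv(fh, index=False)
    return path


def read_cloud_csv(path: str | Path) -> PhasorCloud:
    path = Path(path)
    grid_shape = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("# grid_shape:"):
                grid_shape = tuple(int(x) for x in line.split(":")[1].split())
            if not line.startswith("#"):
                break
    if grid_shape is None:
        raise FormatError("cloud CSV lacks a '# grid_shape:' header line")
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    return PhasorCloud(
        voxel_ids=df["voxel_id"].to_numpy(int),
        axis1=df["axis1"].to_numpy(float),
        axis2=df["axis2"].to_numpy(float),
        grid_shape=grid_shape,
    )


def write_provenance(params: dict, path: str | Path) -> Path:
    """Echo run parameters so a run is reproducible from this file alone."""
    path = Path(path)

    def _default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return str(o)

    path.write_text(json.dumps(params, indent=2, default=_default, sort_keys=True))
    return path


def plot_phasor(cloud: PhasorCloud, reference=None, path: str | Path | None = None):
    """Quick-look phasor plot (PNG) of a cloud and its reference curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.plot(cloud.axis1, cloud.axis2, "k.", ms=3, alpha=0.6, label="voxels")
    if reference is not None and reference.projected is not None:
        ax.plot(reference.projected[:, 0], reference.projected[:, 1], "g-", lw=1,
                label="mono-exponential reference")
    ax.set_xlabel("Axis1")
    ax.set_ylabel("Axis2")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
        return Path(path)
    return fig
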