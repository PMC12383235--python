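"""Readers and writers for all interchange formats.

Formats: multi-page 32-bit float TIFF with a JSON sidecar for AFM height
series; MRC2014 (via gemmi) for density images/volumes, voxel size in the
header; CSV for traces, curves and measurement tables; JSON for ground
truth and reports.  Physical calibration is mandatory on read — there is
no silent pixel-unit fallback.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .containers import CalibrationError, CurrentTrace, DensityField, HeightMapSeries, KineticCurve

__all__ = [
    "write_heightmap_series",
    "read_heightmap_series",
    "write_density_mrc",
    "read_density_mrc",
    "write_trace_csv",
    "read_trace_csv",
    "write_curve_csv",
    "read_curve_csv",
    "write_json",
    "read_json",
]

PathLike = Union[str, Path]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_heightmap_series(path: PathLike, series: HeightMapSeries) -> None:
    """Multi-page float32 TIFF plus JSON sidecar with calibration."""
    import tifffile

    path = Path(path)
    tifffile.imwrite(path, series.frames.astype(np.float32), photometric="minisblack")
    meta = {
        "pixel_size_nm": series.pixel_size,
        "frame_interval_min": series.frame_interval,
        "timestamps_min": list(map(float, series.timestamps)),
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_heightmap_series(path: PathLike) -> HeightMapSeries:
    import tifffile

    path = Path(path)
    side = _sidecar(path)
    if not side.exists():
        raise CalibrationError(f"missing calibration sidecar {side.name}")
    meta = json.loads(side.read_text())
    frames = np.asarray(tifffile.imread(path), dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    return HeightMapSeries(
        frames,
        float(meta["pixel_size_nm"]),
        float(meta["frame_interval_min"]),
        np.asarray(meta["timestamps_min"], dtype=float),
    )


def write_density_mrc(path: PathLike, field: DensityField) -> None:
    """MRC2014 map with the voxel size encoded in the cell header."""
    import gemmi

    grid3 = field.grid if field.rank == 3 else field.grid[None]
    g = gemmi.FloatGrid(*[int(n) for n in grid3.shape[::-1]])
    # gemmi grids are x-fastest; our arrays are (z, y, x)
    arr = np.array(g, copy=False)
    arr[...] = np.ascontiguousarray(np.transpose(grid3, (2, 1, 0)).astype(np.float32))
    vx_a = field.voxel_size * 10.0  # nm -> angstrom for the header cell
    g.set_unit_cell(gemmi.UnitCell(grid3.shape[2] * vx_a, grid3.shape[1] * vx_a,
                                   grid3.shape[0] * vx_a, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    m.write_ccp4_map(str(path))


def read_density_mrc(path: PathLike) -> DensityField:
    import gemmi

    m = gemmi.read_ccp4_map(str(path))
    grid = np.array(m.grid, copy=True)  # (x, y, z) order
    nx = m.grid.nu
    vx_a = m.grid.unit_cell.a / nx
    if vx_a <= 0:
        raise CalibrationError("MRC header carries no voxel size")
    arr = np.transpose(grid, (2, 1, 0)).astype(float)  # -> (z, y, x)
    if arr.shape[0] == 1:
        arr = arr[0]
    return DensityField(arr, vx_a / 10.0)


def write_trace_csv(path: PathLike, trace: CurrentTrace) -> None:
    df = pd.DataFrame({"time_ms": trace.t, "current_pA": trace.i, "voltage_mV": trace.v})
    df.to_csv(path, index=False)
    meta = {"sampling_rate_hz": trace.sampling_rate}
    if trace.filter_cutoff is not None:
        meta["filter_cutoff_hz"] = trace.filter_cutoff
    _sidecar(Path(path)).write_text(json.dumps(meta, indent=1))


def read_trace_csv(path: PathLike) -> CurrentTrace:
    path = Path(path)
    df = pd.read_csv(path)
    required = {"time_ms", "current_pA", "voltage_mV"}
    if not required.issubset(df.columns):
        raise ValueError(f"trace CSV must have columns {sorted(required)} (file {path.name})")
    if len(df) == 0:
        raise ValueError(f"no samples in {path.name}")
    side = _sidecar(path)
    cutoff = None
    if side.exists():
        meta = json.loads(side.read_text())
        fs = float(meta["sampling_rate_hz"])
        cutoff = meta.get("filter_cutoff_hz")
    else:
        dt_ms = np.median(np.diff(df["time_ms"].to_numpy()))
        if not dt_ms > 0:
            raise CalibrationError(f"cannot infer sampling rate from {path.name}")
        fs = 1000.0 / float(dt_ms)
    return CurrentTrace(
        df["time_ms"].to_numpy(float), df["current_pA"].to_numpy(float),
        df["voltage_mV"].to_numpy(float), fs, cutoff,
    )


def write_curve_csv(path: PathLike, curve: KineticCurve) -> None:
    pd.DataFrame({f"time_{curve.time_unit}": curve.t, "fluorescence_au": curve.f}).to_csv(
        path, index=False
    )


def read_curve_csv(path: PathLike) -> KineticCurve:
    df = pd.read_csv(path)
    tcols = [c for c in df.columns if c.startswith("time_")]
    if not tcols or "fluorescence_au" not in df.columns:
        raise ValueError("curve CSV needs a time_<unit> column and fluorescence_au")
    if len(df) == 0:
        raise ValueError("no samples in curve CSV")
    unit = tcols[0].split("_", 1)[1]
    return KineticCurve(df[tcols[0]].to_numpy(float), df["fluorescence_au"].to_numpy(float), unit)


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        return super().default(o)


def write_json(path: PathLike, obj: dict) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, sort_keys=True, cls=_NumpyEncoder))


def read_json(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
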