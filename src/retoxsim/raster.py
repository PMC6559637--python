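"""Minimal ESRI ASCII grid (.asc) reader/writer.

The pipeline exchanges layer-boundary surface maps and result maps as plain
ESRI ASCII rasters: a six-line header (ncols, nrows, xllcorner, yllcorner,
cellsize, NODATA_value) followed by rows of values, first row northernmost.
Internally rasters are float arrays indexed [iy, ix] with iy increasing
northward, plus a validity mask.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = ["SurfaceRaster", "read_ascii_grid", "write_ascii_grid"]

_NODATA = -9999.0


@dataclass
class SurfaceRaster:
    """One 2D height/thickness raster (μm) on a regular grid."""

    values: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("raster values must be 2D")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape mismatch")


def write_ascii_grid(path: str | Path, raster: SurfaceRaster) -> None:
    v = np.where(raster.mask & np.isfinite(raster.values), raster.values, _NODATA)
    header = (
        f"ncols {v.shape[1]}\n"
        f"nrows {v.shape[0]}\n"
        f"xllcorner {raster.origin[0]:.6f}\n"
        f"yllcorner {raster.origin[1]:.6f}\n"
        f"cellsize {raster.spacing:.6f}\n"
        f"NODATA_value {_NODATA:.1f}\n"
    )
    with open(path, "w") as fh:
        fh.write(header)
        np.savetxt(fh, v[::-1], fmt="%.8g")  # rows north->south on disk


def read_ascii_grid(path: str | Path) -> SurfaceRaster:
    with open(path) as fh:
        header = {}
        for _ in range(6):
            key, val = fh.readline().split()
            header[key.lower()] = float(val)
        data = np.loadtxt(fh, ndmin=2)
    ncols, nrows = int(header["ncols"]), int(header["nrows"])
    if data.shape != (nrows, ncols):
        raise ValueError(f"{path}: data shape {data.shape} != header ({nrows}, {ncols})")
    nodata = header.get("nodata_value", _NODATA)
    v = data[::-1].copy()  # back to south->north
    mask = v != nodata
    v[~mask] = np.nan
    return SurfaceRaster(
        values=v,
        spacing=header["cellsize"],
        origin=(header["xllcorner"], header["yllcorner"]),
        mask=mask,
    )
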