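"""Export helpers: legacy VTK structured grids, per-slice rasters, JSON.

Fields are written as legacy ASCII VTK structured-points files (readable by
ParaView and friends) carrying concentration (mol/m^3) and pO2 (mmHg) as
two point arrays, or as per-z-slice ESRI ASCII rasters for quick
inspection; balance reports serialize to flat JSON.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np

from .geometry import AxiGrid, DomainLabelField
from .raster import SurfaceRaster, write_ascii_grid
from .solver import BalanceReport, OxygenField

__all__ = ["write_vtk_field", "write_po2_slices", "write_label_slices", "balance_to_json"]


def _grid_spacing(grid) -> tuple[float, float, float]:
    if isinstance(grid, AxiGrid):
        return (grid.dr, 1.0, grid.dz)
    return (grid.spacing_xy, grid.spacing_xy, grid.spacing_z)


def write_vtk_field(field: OxygenField, path: str | Path) -> None:
    """Write a legacy VTK structured-points file with concentration and pO2.

    Axisymmetric fields are written as an (n_r, 1, n_z) slab; 3D fields as
    (n_x, n_y, n_z). Non-tissue points carry -1.
    """
    c = np.nan_to_num(field.concentration, nan=-1.0)
    p = np.nan_to_num(field.po2(), nan=-1.0)
    if c.ndim == 2:
        c = c[:, None, :]
        p = p[:, None, :]
    nx, ny, nz = c.shape
    dx, dy, dz = _grid_spacing(field.grid)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nretinal oxygen field\nASCII\n")
        fh.write("DATASET STRUCTURED_POINTS\n")
        fh.write(f"DIMENSIONS {nx} {ny} {nz}\n")
        fh.write("ORIGIN 0 0 0\n")
        fh.write(f"SPACING {dx:g} {dy:g} {dz:g}\n")
        fh.write(f"POINT_DATA {nx * ny * nz}\n")
        for name, arr in (("concentration_mol_m3", c), ("po2_mmHg", p)):
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            # VTK expects x fastest, z slowest
            flat = np.transpose(arr, (2, 1, 0)).ravel()
            np.savetxt(fh, flat, fmt="%.6g")


def write_po2_slices(field: OxygenField, directory: str | Path, every: int = 1) -> list[Path]:
    """Write pO2 (mmHg) per z-slice as ESRI ASCII rasters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    p = field.po2()
    if p.ndim == 2:
        p = p[:, None, :]
    dx, _, _ = _grid_spacing(field.grid)
    out = []
    for k in range(0, p.shape[2], every):
        path = directory / f"po2_z{k:04d}.asc"
        write_ascii_grid(path, SurfaceRaster(p[:, :, k].T, spacing=dx))
        out.append(path)
    return out


def write_label_slices(domains: DomainLabelField, directory: str | Path, every: int = 1) -> list[Path]:
    """Write the integer domain labels per z-slice as ESRI ASCII rasters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    lab = domains.labels
    if lab.ndim == 2:
        lab = lab[:, None, :]
    dx, _, _ = _grid_spacing(domains.grid)
    out = []
    for k in range(0, lab.shape[2], every):
        path = directory / f"labels_z{k:04d}.asc"
        write_ascii_grid(path, SurfaceRaster(lab[:, :, k].T.astype(float), spacing=dx))
        out.append(path)
    return out


def balance_to_json(report: BalanceReport, path: str | Path) -> None:
    Path(path).write_text(json.dumps(asdict(report), indent=1))
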