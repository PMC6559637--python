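"""In-silico outer-retinal geometry.

Two discrete representations are used:

* an axisymmetric (r, z) structured grid for generic single-druse studies
  (a hemisphere or an on-axis cylinder is rotationally symmetric, which makes
  threshold searches orders of magnitude cheaper than full 3D), and
* a 3D structured grid built from a stack of six layer-boundary surface
  rasters, the representation used by the patient-style pipeline.

The tissue column, basal to apical, is: Bruch's membrane (BrM) | drusen |
RPE + outer segments | inner segments (IS) | ONL + OPL.  Only the IS
consumes oxygen; every other domain is a passive diffusive slab sharing the
same diffusion coefficient, so the split between the passive labels is
bookkeeping, not physics.  Drusen sit on top of BrM and displace everything
above them vertically, preserving each layer's local thickness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Sequence

import numpy as np

from .units_params import ModelParams

__all__ = [
    "Label",
    "AxiGrid",
    "Grid3D",
    "DruseSpec",
    "DomainLabelField",
    "LayerSurfaceStack",
    "build_generic_domains",
    "druse_height_profile",
    "insert_druse",
    "surfaces_to_domains",
    "render_generic_stack",
]

#: Thickness (μm) of the BrM band carved out of the merged 55 μm
#: BrM+RPE+OS slab in the generic model.  Purely a labeling convention so
#: drusen can sit between BrM and RPE; transport is unaffected because all
#: passive domains share D.
BRM_THICKNESS_UM = 4.0


class Label(IntEnum):
    OUTSIDE = 0
    BRM = 1
    DRUSEN = 2
    RPE_OS = 3
    IS = 4
    ONL_OPL = 5


@dataclass(frozen=True)
class AxiGrid:
    """Cell-centered axisymmetric (r, z) grid; r = 0 is the symmetry axis.

    ``spacing`` is the axial (z) cell size in μm; ``spacing_r`` defaults to
    it but may be coarser for very wide geometries where lateral gradients
    are gentle.
    """

    n_r: int
    n_z: int
    spacing: float
    spacing_r: float | None = None

    def __post_init__(self):
        if self.n_r < 4 or self.n_z < 4:
            raise ValueError("grid must have at least 4 cells per direction")
        if self.spacing <= 0 or (self.spacing_r is not None and self.spacing_r <= 0):
            raise ValueError("grid spacing must be positive")

    @property
    def dr(self) -> float:
        return self.spacing if self.spacing_r is None else self.spacing_r

    @property
    def dz(self) -> float:
        return self.spacing

    @property
    def r_max(self) -> float:
        return self.n_r * self.dr

    @property
    def z_max(self) -> float:
        return self.n_z * self.dz

    @property
    def r_centers(self) -> np.ndarray:
        return (np.arange(self.n_r) + 0.5) * self.dr

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.n_z) + 0.5) * self.dz


@dataclass(frozen=True)
class Grid3D:
    """Cell-centered 3D grid; z increases from basal (choroid) to apical."""

    n_x: int
    n_y: int
    n_z: int
    spacing_xy: float
    spacing_z: float
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if min(self.n_x, self.n_y, self.n_z) < 4:
            raise ValueError("grid must have at least 4 cells per direction")
        if self.spacing_xy <= 0 or self.spacing_z <= 0:
            raise ValueError("grid spacing must be positive")

    @property
    def z_centers(self) -> np.ndarray:
        return (np.arange(self.n_z) + 0.5) * self.spacing_z


@dataclass(frozen=True)
class DruseSpec:
    """One druse: a hemisphere (hard druse) or a squat cylinder (soft druse).

    The hemisphere's height is diameter/2 by construction and the ``height``
    field is ignored; the cylinder's height and diameter vary independently.
    """

    shape: str
    diameter: float
    height: float | None = None
    center_xy: tuple[float, float] | None = None

    def __post_init__(self):
        if self.shape not in ("hemisphere", "cylinder"):
            raise ValueError(f"unknown druse shape {self.shape!r}")
        if self.diameter <= 0:
            raise ValueError("druse diameter must be positive")
        if self.shape == "cylinder" and (self.height is None or self.height <= 0):
            raise ValueError("cylinder druse requires a positive height")

    @property
    def apex_height(self) -> float:
        return self.diameter / 2.0 if self.shape == "hemisphere" else float(self.height)


@dataclass
class DomainLabelField:
    """Per-cell tissue-domain labels on a structured grid.

    ``labels`` has shape (n_r, n_z) on an :class:`AxiGrid` and
    (n_x, n_y, n_z) on a :class:`Grid3D`; values are :class:`Label` codes.
    """

    grid: AxiGrid | Grid3D
    labels: np.ndarray

    def __post_init__(self):
        expect = (
            (self.grid.n_r, self.grid.n_z)
            if isinstance(self.grid, AxiGrid)
            else (self.grid.n_x, self.grid.n_y, self.grid.n_z)
        )
        if tuple(self.labels.shape) != expect:
            raise ValueError(f"labels shape {self.labels.shape} != grid shape {expect}")

    @property
    def tissue_mask(self) -> np.ndarray:
        return self.labels != Label.OUTSIDE


_LAYER_NAMES = ("brm_top", "druse_top", "rpe_os_top", "is_top", "onl_opl_top")


def _labels_from_boundaries(z_centers: np.ndarray, bounds: np.ndarray, z_base=None) -> np.ndarray:
    """Label cells by which boundary pair brackets their center.

    ``bounds`` has shape cols + (5,): cumulative upper boundaries of BRM,
    DRUSEN, RPE_OS, IS, ONL_OPL above the local base (z = 0 or ``z_base``).
    Returns an integer array of shape cols + (n_z,).
    """
    zc = z_centers.reshape((1,) * (bounds.ndim - 1) + (-1,))
    if z_base is not None:
        zc = zc - np.asarray(z_base)[..., None]
    b = bounds[..., None, :]  # cols x 1 x 5
    # number of boundaries strictly below the cell center -> label index
    idx = (zc[..., None] >= b).sum(axis=-1)
    out = np.where(idx >= 5, int(Label.OUTSIDE), idx + 1)
    out = np.where(zc < 0, int(Label.OUTSIDE), out)
    return out.astype(np.int8)


def generic_boundaries(params: ModelParams, druse_height: np.ndarray | float = 0.0) -> np.ndarray:
    """Cumulative layer boundary heights (μm) for the generic laminar model,
    optionally with a local druse of the given height inserted above BrM."""
    h = np.asarray(druse_height, dtype=float)
    brm = np.broadcast_to(np.float64(BRM_THICKNESS_UM), h.shape).copy()
    bounds = np.stack(
        [
            brm,
            brm + h,
            h + params.height_sub_is,
            h + params.height_sub_is + params.height_is,
            h + params.height_sub_is + params.height_is + params.height_onl_opl,
        ],
        axis=-1,
    )
    return bounds


def build_generic_domains(params: ModelParams, grid: AxiGrid | Grid3D) -> DomainLabelField:
    """Flat laminar geometry: BrM+RPE+OS slab, IS, ONL+OPL, OUTSIDE above."""
    total = params.height_sub_is + params.height_is + params.height_onl_opl
    if grid.z_centers[-1] + (grid.dz if isinstance(grid, AxiGrid) else grid.spacing_z) / 2 < total:
        raise ValueError(f"grid z-extent must cover the {total:.0f} μm tissue column")
    if isinstance(grid, AxiGrid):
        bounds = np.broadcast_to(generic_boundaries(params), (grid.n_r, 5))
    else:
        bounds = np.broadcast_to(generic_boundaries(params), (grid.n_x, grid.n_y, 5))
    return DomainLabelField(grid, _labels_from_boundaries(grid.z_centers, bounds))


def druse_height_profile(spec: DruseSpec, r) -> np.ndarray | float:
    """Local druse height (μm) at radial distance r (μm) from the druse axis."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("radial distance must be non-negative")
    a = spec.diameter / 2.0
    if spec.shape == "hemisphere":
        h = np.where(r <= a, np.sqrt(np.maximum(a * a - r * r, 0.0)), 0.0)
    else:
        h = np.where(r <= a, float(spec.height), 0.0)
    return float(h) if h.ndim == 0 else h


def insert_druse(params: ModelParams, druse: DruseSpec, grid: AxiGrid) -> DomainLabelField:
    """Generic laminar field with one on-axis druse displacing overlying layers.

    The displacement is purely vertical: every boundary above the druse is
    shifted up by the local druse height, so each layer's thickness is
    preserved column by column.
    """
    total = params.height_sub_is + params.height_is + params.height_onl_opl
    need = total + druse.apex_height
    if grid.n_z * grid.dz < need:
        raise ValueError(f"grid z-extent {grid.n_z * grid.dz:.0f} μm < required {need:.0f} μm")
    h = druse_height_profile(druse, grid.r_centers)
    bounds = generic_boundaries(params, h)
    return DomainLabelField(grid, _labels_from_boundaries(grid.z_centers, bounds))


@dataclass
class LayerSurfaceStack:
    """Six ordered boundary-height rasters describing one eye at one time.

    ``surfaces`` has shape (6, n_y, n_x) in μm; surface j and j+1 bracket,
    basal to apical: BrM, drusen, RPE+OS, IS, ONL+OPL.  ``mask`` is True on
    valid pixels; all six rasters share grid and mask.
    """

    surfaces: np.ndarray
    spacing: float
    origin: tuple[float, float] = (0.0, 0.0)
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.surfaces = np.asarray(self.surfaces, dtype=float)
        if self.surfaces.ndim != 3 or self.surfaces.shape[0] != 6:
            raise ValueError("surfaces must have shape (6, n_y, n_x)")
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if self.mask is None:
            self.mask = np.ones(self.surfaces.shape[1:], dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.surfaces.shape[1:]:
            raise ValueError("mask shape does not match surfaces")

    @property
    def shape(self) -> tuple[int, int]:
        return self.surfaces.shape[1:]

    def validate_ordering(self, tol: float = 1e-9):
        """Raise if any unmasked pixel has out-of-order surfaces."""
        d = np.diff(self.surfaces, axis=0)
        bad = (d < -tol).any(axis=0) & self.mask
        if bad.any():
            iy, ix = np.argwhere(bad)[0]
            raise ValueError(
                f"surface ordering violated at {int(bad.sum())} pixels, "
                f"first at (iy={iy}, ix={ix})"
            )

    def thickness(self, lower: int, upper: int) -> np.ndarray:
        """Thickness raster (μm) between surface indices lower and upper."""
        t = self.surfaces[upper] - self.surfaces[lower]
        return np.where(self.mask, t, np.nan)

    @property
    def onl_opl_thickness(self) -> np.ndarray:
        return self.thickness(4, 5)

    @property
    def druse_height(self) -> np.ndarray:
        return self.thickness(1, 2)

    @property
    def sub_rpe_thickness(self) -> np.ndarray:
        """BrM + drusen thickness (z2 - z0), the registration channel."""
        return self.thickness(0, 2)

    @property
    def rpe_drusen_brm_thickness(self) -> np.ndarray:
        """BrM + drusen + RPE/OS thickness (z3 - z0), the drusen-height
        predictor used in the spatial statistics."""
        return self.thickness(0, 3)

    @property
    def total_thickness(self) -> np.ndarray:
        return self.thickness(0, 5)

    def copy(self) -> "LayerSurfaceStack":
        return LayerSurfaceStack(
            self.surfaces.copy(), self.spacing, self.origin, self.mask.copy(), dict(self.meta)
        )


def surfaces_to_domains(stack: LayerSurfaceStack, grid: Grid3D) -> DomainLabelField:
    """Label each 3D grid cell by which surface pair brackets its center.

    Grid columns are matched to stack pixels by nearest center; nodata
    columns are OUTSIDE.  Zero-thickness layers simply contribute no cells.
    """
    stack.validate_ordering()
    ny, nx = stack.shape
    # nearest stack pixel per grid column
    gx = grid.origin[0] + (np.arange(grid.n_x) + 0.5) * grid.spacing_xy
    gy = grid.origin[1] + (np.arange(grid.n_y) + 0.5) * grid.spacing_xy
    ix = np.clip(np.round((gx - stack.origin[0]) / stack.spacing - 0.5).astype(int), 0, nx - 1)
    iy = np.clip(np.round((gy - stack.origin[1]) / stack.spacing - 0.5).astype(int), 0, ny - 1)
    surf = stack.surfaces[:, iy, :][:, :, ix]  # (6, n_y_grid, n_x_grid)
    surf = np.transpose(surf, (2, 1, 0))  # (n_x, n_y, 6)
    base = surf[..., 0]
    bounds = surf[..., 1:] - base[..., None]  # cumulative above base
    labels = _labels_from_boundaries(grid.z_centers, bounds, z_base=base)
    valid = stack.mask[iy, :][:, ix].T  # (n_x, n_y)
    labels[~valid] = int(Label.OUTSIDE)
    return DomainLabelField(grid, labels)


def render_generic_stack(
    params: ModelParams,
    n_x: int,
    n_y: int,
    spacing: float,
    drusen: Sequence[DruseSpec] = (),
    base_height: np.ndarray | float = 0.0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> LayerSurfaceStack:
    """Render a generic laminar geometry (plus optional drusen) as a
    six-surface stack — the bridge between the generic model and the
    surface-stack pipeline, also used to cross-check the two solvers."""
    xs = origin[0] + (np.arange(n_x) + 0.5) * spacing
    ys = origin[1] + (np.arange(n_y) + 0.5) * spacing
    X, Y = np.meshgrid(xs, ys)  # (n_y, n_x)
    h = np.zeros((n_y, n_x))
    for d in drusen:
        if d.center_xy is None:
            raise ValueError("druse in a 3D stack needs center_xy")
        r = np.hypot(X - d.center_xy[0], Y - d.center_xy[1])
        h = np.maximum(h, druse_height_profile(d, r))
    z0 = np.broadcast_to(np.asarray(base_height, dtype=float), (n_y, n_x)).astype(float)
    z1 = z0 + BRM_THICKNESS_UM
    z2 = z1 + h
    z3 = z0 + h + params.height_sub_is
    z4 = z3 + params.height_is
    z5 = z4 + params.height_onl_opl
    return LayerSurfaceStack(np.stack([z0, z1, z2, z3, z4, z5]), spacing, origin)
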