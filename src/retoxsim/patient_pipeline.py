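"""From segmented layer-surface stacks to hypoxia and thinning maps.

One eye is described by two :class:`~retoxsim.geometry.LayerSurfaceStack`
objects (baseline and follow-up).  The pipeline mirrors a clinical OCT
workflow: co-register the two time points on the sub-RPE thickness channel,
crop a square window centered at the deepest foveal spot, flatten to the
basal surface, reconstruct the (unresolvable) IS thickness from the
overlying ONL+OPL, solve the 3D oxygen model on the baseline geometry,
down-sample to a 150 x 150 x 20 matrix and take per-column minima, and
difference the ONL+OPL thickness between time points on the registered
grid.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import Grid3D, LayerSurfaceStack, surfaces_to_domains
from .raster import SurfaceRaster, read_ascii_grid, write_ascii_grid
from .solver import OxygenField, SolverSettings, solve_steady_state
from .units_params import ModelParams

log = logging.getLogger(__name__)

__all__ = [
    "RegistrationResult",
    "MinO2Map",
    "ThinningMap",
    "read_surface_stack",
    "write_surface_stack",
    "register_timepoints",
    "crop_to_window",
    "flatten_to_baseline",
    "reconstruct_is",
    "run_patient_model",
    "thinning_map",
]

_SURFACE_FILES = ["z0_brm_base", "z1_brm_top", "z2_druse_top", "z3_rpe_os_top", "z4_is_top", "z5_onl_opl_top"]

#: output map dimensions (XY) and per-column Z samples
MAP_DIMS = (150, 150)
N_Z_SAMPLES = 20
#: registration confidence floor: optima with Pearson r below this are flagged
LOW_CONFIDENCE_R = 0.5


@dataclass(frozen=True)
class RegistrationResult:
    """Rigid in-plane transform aligning a follow-up map to baseline."""

    rotation: float  # degrees about the window center
    translation: tuple[float, float]  # (dx, dy) μm
    pearson_r_at_optimum: float
    low_confidence: bool = False


@dataclass
class MinO2Map:
    """150x150 map of per-column minimum pO2 (mmHg)."""

    values: np.ndarray
    eye_id: str = ""
    timepoint: str = ""

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != MAP_DIMS:
            raise ValueError(f"MinO2Map must be {MAP_DIMS}, got {self.values.shape}")
        if np.nanmin(self.values) < 0:
            raise ValueError("negative pO2 in MinO2Map")


@dataclass
class ThinningMap:
    """150x150 map of Δ(ONL+OPL) thickness in μm (negative = thinning)."""

    values: np.ndarray
    eye_id: str = ""
    interval: str = ""
    low_confidence: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != MAP_DIMS:
            raise ValueError(f"ThinningMap must be {MAP_DIMS}, got {self.values.shape}")


# ----------------------------------------------------------------- stack I/O

def write_surface_stack(stack: LayerSurfaceStack, directory: str | Path, overwrite: bool = False) -> Path:
    """Write six .asc rasters plus a JSON manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = directory / "manifest.json"
    if manifest.exists() and not overwrite:
        raise FileExistsError(f"{manifest} exists (pass overwrite=True)")
    files = []
    for name, surf in zip(_SURFACE_FILES, stack.surfaces):
        fname = f"{name}.asc"
        write_ascii_grid(
            directory / fname,
            SurfaceRaster(np.where(stack.mask, surf, np.nan), stack.spacing, stack.origin),
        )
        files.append(fname)
    doc = {"surfaces_basal_to_apical": files, "spacing_um": stack.spacing, **stack.meta}
    manifest.write_text(json.dumps(doc, indent=1))
    return manifest


def read_surface_stack(manifest_path: str | Path, max_disorder_frac: float = 0.01) -> LayerSurfaceStack:
    """Read and validate a six-surface stack from its manifest.

    Pixels with out-of-order surfaces are repaired by local reordering when
    they are rare (<= ``max_disorder_frac`` of unmasked pixels, logged);
    beyond that the stack is rejected.
    """
    manifest_path = Path(manifest_path)
    doc = json.loads(manifest_path.read_text())
    rasters = [read_ascii_grid(manifest_path.parent / f) for f in doc["surfaces_basal_to_apical"]]
    if len(rasters) != 6:
        raise ValueError("manifest must list exactly six surfaces")
    r0 = rasters[0]
    for f, r in zip(doc["surfaces_basal_to_apical"][1:], rasters[1:]):
        if r.values.shape != r0.values.shape or r.spacing != r0.spacing:
            raise ValueError(f"raster {f} does not match shape/spacing of {doc['surfaces_basal_to_apical'][0]}")
    surfaces = np.stack([r.values for r in rasters])
    mask = np.logical_and.reduce([r.mask for r in rasters])
    disordered = (np.diff(surfaces, axis=0) < -1e-9).any(axis=0) & mask
    n_bad = int(disordered.sum())
    if n_bad:
        frac = n_bad / max(int(mask.sum()), 1)
        if frac > max_disorder_frac:
            raise ValueError(
                f"surface ordering violated at {n_bad} pixels ({frac:.1%} of unmasked)"
            )
        log.warning("repairing surface ordering at %d pixels by local sort", n_bad)
        iy, ix = np.nonzero(disordered)
        surfaces[:, iy, ix] = np.sort(surfaces[:, iy, ix], axis=0)
    meta = {k: v for k, v in doc.items() if k not in ("surfaces_basal_to_apical", "spacing_um")}
    stack = LayerSurfaceStack(surfaces, r0.spacing, r0.origin, mask, meta)
    stack.validate_ordering()
    return stack


# -------------------------------------------------------------- registration

def _transform_raster(values: np.ndarray, rotation_deg: float, shift_px: tuple[int, int]) -> np.ndarray:
    """Rotate about the raster center then shift by whole pixels; NaN fill."""
    out = values.astype(float)
    if rotation_deg != 0.0:
        out = ndimage.rotate(out, rotation_deg, reshape=False, order=1, mode="constant", cval=np.nan)
    dy, dx = shift_px[1], shift_px[0]
    shifted = np.full_like(out, np.nan)
    ys = slice(max(dy, 0), out.shape[0] + min(dy, 0))
    xs = slice(max(dx, 0), out.shape[1] + min(dx, 0))
    ys_src = slice(max(-dy, 0), out.shape[0] + min(-dy, 0))
    xs_src = slice(max(-dx, 0), out.shape[1] + min(-dx, 0))
    shifted[ys, xs] = out[ys_src, xs_src]
    return shifted


def _masked_pearson(a: np.ndarray, b: np.ndarray) -> tuple[float, int]:
    m = np.isfinite(a) & np.isfinite(b)
    n = int(m.sum())
    if n < 3:
        return -np.inf, n
    x, y = a[m], b[m]
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x * x).sum() * (y * y).sum())
    if denom == 0:
        return -np.inf, n
    return float((x * y).sum() / denom), n


def register_timepoints(
    thick_a: SurfaceRaster,
    thick_b: SurfaceRaster,
    rotation_range: float = 3.0,
    rotation_step: float = 0.25,
    translation_range: float = 300.0,
) -> RegistrationResult:
    """Exhaustive grid search for the rigid transform of map B that best
    matches map A by Pearson correlation on the overlap.

    Rotation is about the window center; translation moves in whole pixels.
    Candidates with less than 50% pixel overlap are discarded; ties break
    toward the smallest |rotation|, then smallest |dx|+|dy|.
    """
    if thick_a.spacing != thick_b.spacing:
        raise ValueError("thickness maps must share spacing")
    sp = thick_a.spacing
    a = np.where(thick_a.mask, thick_a.values, np.nan)
    b = np.where(thick_b.mask, thick_b.values, np.nan)
    n_valid = int(np.isfinite(a).sum())
    max_px = int(round(translation_range / sp))
    n_rot = int(round(rotation_range / rotation_step))
    rotations = sorted(
        (k * rotation_step for k in range(-n_rot, n_rot + 1)), key=lambda r: (abs(r), r)
    )
    shifts = sorted(
        ((dx, dy) for dx in range(-max_px, max_px + 1) for dy in range(-max_px, max_px + 1)),
        key=lambda s: (abs(s[0]) + abs(s[1]), s),
    )
    best = None
    any_candidate = False
    for rot in rotations:
        rb = _transform_raster(b, rot, (0, 0))
        for dx, dy in shifts:
            tb = _transform_raster(rb, 0.0, (dx, dy))
            r, n = _masked_pearson(a, tb)
            if n < 0.5 * n_valid:
                continue
            any_candidate = True
            if best is None or r > best[0] + 1e-15:
                best = (r, rot, dx, dy)
    if not any_candidate:
        raise RuntimeError("no registration candidate achieved 50% overlap")
    r, rot, dx, dy = best
    return RegistrationResult(
        rotation=rot,
        translation=(dx * sp, dy * sp),
        pearson_r_at_optimum=r,
        low_confidence=r < LOW_CONFIDENCE_R,
    )


def apply_registration(raster: SurfaceRaster, reg: RegistrationResult) -> SurfaceRaster:
    """Apply a registration transform to a raster (rotate, then shift)."""
    sp = raster.spacing
    shift_px = (int(round(reg.translation[0] / sp)), int(round(reg.translation[1] / sp)))
    v = _transform_raster(np.where(raster.mask, raster.values, np.nan), reg.rotation, shift_px)
    return SurfaceRaster(v, sp, raster.origin)


def align_stack(stack: LayerSurfaceStack, reg: RegistrationResult) -> LayerSurfaceStack:
    """Apply a registration transform to every surface of a stack."""
    sp = stack.spacing
    shift_px = (int(round(reg.translation[0] / sp)), int(round(reg.translation[1] / sp)))
    surfaces = np.stack(
        [
            _transform_raster(np.where(stack.mask, s, np.nan), reg.rotation, shift_px)
            for s in stack.surfaces
        ]
    )
    mask = np.isfinite(surfaces).all(axis=0)
    surfaces = np.where(mask, surfaces, 0.0)
    return LayerSurfaceStack(surfaces, sp, stack.origin, mask, dict(stack.meta))


def _crop_at(stack: LayerSurfaceStack, center_px: tuple[int, int], window_um: float, z_window_um: float = 400.0) -> LayerSurfaceStack:
    n_px = int(round(window_um / stack.spacing))
    iy, ix = center_px
    ny, nx = stack.shape
    y0, x0 = iy - n_px // 2, ix - n_px // 2
    if y0 < 0 or x0 < 0 or y0 + n_px > ny or x0 + n_px > nx:
        raise ValueError("window exceeds stack extent")
    out = LayerSurfaceStack(
        stack.surfaces[:, y0 : y0 + n_px, x0 : x0 + n_px].copy(),
        stack.spacing,
        (stack.origin[0] + x0 * stack.spacing, stack.origin[1] + y0 * stack.spacing),
        stack.mask[y0 : y0 + n_px, x0 : x0 + n_px].copy(),
        dict(stack.meta),
    )
    out.meta["z_window_um"] = z_window_um
    return out


def process_eye(
    stack_t0: LayerSurfaceStack,
    stack_t1: LayerSurfaceStack,
    params: ModelParams,
    settings: SolverSettings | None = None,
    window_um: float = 3000.0,
    spacing_z: float = 2.0,
    map_dims: tuple[int, int] = MAP_DIMS,
) -> dict:
    """End-to-end analysis of one eye's two time points.

    Registers t1 to t0 on the sub-RPE thickness channel, crops both stacks
    at t0's fovea, solves the baseline oxygen model, and returns the
    co-registered minimum-pO2, drusen-height, and thinning maps together
    with the registration result.
    """
    reg = register_timepoints(
        SurfaceRaster(stack_t0.sub_rpe_thickness, stack_t0.spacing, stack_t0.origin),
        SurfaceRaster(stack_t1.sub_rpe_thickness, stack_t1.spacing, stack_t1.origin),
    )
    t1_aligned = align_stack(stack_t1, reg)
    center = find_fovea(stack_t0)
    crop_t0 = _crop_at(stack_t0, center, window_um)
    crop_t1 = _crop_at(t1_aligned, center, window_um)
    prepared = reconstruct_is(flatten_to_baseline(crop_t0))
    field, min_o2 = run_patient_model(prepared, params, settings, spacing_z, map_dims)
    thin = thinning_map(crop_t0, crop_t1, reg=None, map_dims=map_dims)
    thin.low_confidence = reg.low_confidence
    druse_map = _resample_xy(np.where(crop_t0.mask, crop_t0.rpe_drusen_brm_thickness, np.nan).T, map_dims)
    return {
        "registration": reg,
        "crop_t0": crop_t0,
        "crop_t1": crop_t1,
        "field": field,
        "min_o2": min_o2,
        "thinning": thin,
        "druse_height_map": druse_map,
    }


# ------------------------------------------------------------- stack reshaping

def find_fovea(stack: LayerSurfaceStack, smooth: int = 5) -> tuple[int, int]:
    """Pixel (iy, ix) of the deepest foveal spot: the unmasked minimum of the
    5x5-median-smoothed total retinal thickness."""
    t = stack.total_thickness
    t_s = ndimage.median_filter(np.where(stack.mask, t, np.nan), size=smooth)
    t_s = np.where(stack.mask & np.isfinite(t_s), t_s, np.inf)
    iy, ix = np.unravel_index(np.argmin(t_s), t_s.shape)
    return int(iy), int(ix)


def crop_to_window(
    stack: LayerSurfaceStack, window_um: float = 3000.0, z_window_um: float = 400.0
) -> LayerSurfaceStack:
    """Square half-open XY window of the given size centered at the fovea."""
    n_px = int(round(window_um / stack.spacing))
    iy, ix = find_fovea(stack)
    ny, nx = stack.shape
    y0, x0 = iy - n_px // 2, ix - n_px // 2
    if y0 < 0 or x0 < 0 or y0 + n_px > ny or x0 + n_px > nx:
        ach = min(iy, ix, ny - iy, nx - ix) * 2 * stack.spacing
        raise ValueError(
            f"{window_um:.0f} μm window exceeds stack extent around the fovea; "
            f"achievable ≈ {ach:.0f} μm"
        )
    out = LayerSurfaceStack(
        stack.surfaces[:, y0 : y0 + n_px, x0 : x0 + n_px].copy(),
        stack.spacing,
        (stack.origin[0] + x0 * stack.spacing, stack.origin[1] + y0 * stack.spacing),
        stack.mask[y0 : y0 + n_px, x0 : x0 + n_px].copy(),
        dict(stack.meta),
    )
    out.meta["z_window_um"] = z_window_um
    out.meta["fovea_xy_px"] = (ix - x0, iy - y0)
    return out


def flatten_to_baseline(stack: LayerSurfaceStack) -> LayerSurfaceStack:
    """Re-express all surfaces as heights above the basal surface (z0 ≡ 0).

    Thicknesses are untouched.  Tissue above the Z window (default 400 μm,
    set by cropping) is truncated and logged — rare in practice.
    """
    out = stack.copy()
    out.surfaces = out.surfaces - out.surfaces[0]
    z_win = float(out.meta.get("z_window_um", 400.0))
    over = (out.surfaces > z_win) & out.mask
    if over.any():
        log.warning("truncating %d surface samples above the %.0f μm Z window", int(over.sum()), z_win)
        out.surfaces = np.minimum(out.surfaces, z_win)
    return out


def reconstruct_is(stack: LayerSurfaceStack, is_max_um: float = 25.0) -> LayerSurfaceStack:
    """Replace the IS thickness with a linear fraction of the overlying
    ONL+OPL thickness: IS = is_max * T / max(T).

    OCT cannot resolve the IS boundary reliably; the IS below the thickest
    ONL+OPL is assigned the full nominal thickness and everywhere else
    scales linearly.  All other layer thicknesses are preserved.
    """
    t = stack.onl_opl_thickness
    t_max = np.nanmax(np.where(stack.mask, t, np.nan))
    if not np.isfinite(t_max) or t_max <= 0:
        raise ValueError("ONL+OPL thickness is zero everywhere; cannot reconstruct IS")
    is_new = is_max_um * np.where(stack.mask, t, 0.0) / t_max
    out = stack.copy()
    out.surfaces[4] = out.surfaces[3] + is_new
    out.surfaces[5] = out.surfaces[4] + np.where(stack.mask, t, 0.0)
    return out


# ------------------------------------------------------------ model + maps

def _resample_xy(values: np.ndarray, out_dims: tuple[int, int]) -> np.ndarray:
    """Area-weighted XY resampling of a (n_x, n_y, ...) array to out_dims.

    Source columns are binned into output pixels and averaged; output pixels
    receiving no source column fall back to the nearest source column.
    """
    nx, ny = values.shape[:2]
    ox, oy = out_dims
    bx = np.minimum((np.arange(nx) * ox) // nx, ox - 1)
    by = np.minimum((np.arange(ny) * oy) // ny, oy - 1)
    if nx >= ox and ny >= oy:
        out = np.zeros((ox, oy) + values.shape[2:])
        cnt = np.zeros((ox, oy))
        fin = np.isfinite(values).all(axis=tuple(range(2, values.ndim)))
        BX, BY = np.meshgrid(bx, by, indexing="ij")
        np.add.at(out, (BX[fin], BY[fin]), values[fin])
        np.add.at(cnt, (BX[fin], BY[fin]), 1)
        with np.errstate(invalid="ignore", divide="ignore"):
            out = out / cnt.reshape((ox, oy) + (1,) * (values.ndim - 2))
        return out
    # upsampling: nearest source column
    sx = np.minimum((np.arange(ox) * nx) // ox, nx - 1)
    sy = np.minimum((np.arange(oy) * ny) // oy, ny - 1)
    return values[sx][:, sy]


def _column_z_samples(po2: np.ndarray, grid: Grid3D, tops: np.ndarray, n_samples: int) -> np.ndarray:
    """Sample each column's pO2 at n evenly spaced heights through the tissue."""
    nx, ny, _ = po2.shape
    zc = grid.z_centers
    frac = (np.arange(n_samples) + 0.5) / n_samples
    out = np.full((nx, ny, n_samples), np.nan)
    for i in range(nx):
        for j in range(ny):
            col = po2[i, j]
            fin = np.isfinite(col)
            if not fin.any() or tops[i, j] <= 0:
                continue
            zs = frac * tops[i, j]
            out[i, j] = np.interp(zs, zc[fin], col[fin])
    return out


def run_patient_model(
    stack: LayerSurfaceStack,
    params: ModelParams,
    settings: SolverSettings | None = None,
    spacing_z: float = 2.0,
    map_dims: tuple[int, int] = MAP_DIMS,
    n_z_samples: int = N_Z_SAMPLES,
) -> tuple[OxygenField, MinO2Map]:
    """Solve the 3D oxygen model on a prepared stack and reduce to the
    per-column minimum-pO2 map.

    The stack must be cropped, flattened, and IS-reconstructed.  The field
    is sampled at ``n_z_samples`` evenly spaced heights per tissue column,
    area-averaged onto ``map_dims`` in XY, and minimized over Z.
    """
    if np.nanmax(np.abs(stack.surfaces[0][stack.mask])) > 1e-6:
        raise ValueError("stack must be flattened (z0 == 0) before solving")
    top = np.where(stack.mask, stack.surfaces[5], 0.0)
    n_z = max(4, int(np.ceil(np.nanmax(top) / spacing_z)))
    grid = Grid3D(
        n_x=stack.shape[1],
        n_y=stack.shape[0],
        n_z=n_z,
        spacing_xy=stack.spacing,
        spacing_z=spacing_z,
        origin=stack.origin,
    )
    domains = surfaces_to_domains(stack, grid)
    fld = solve_steady_state(domains, params, settings)
    po2 = fld.po2()
    tops = top.T  # (n_x, n_y)
    samples = _column_z_samples(po2, grid, tops, n_z_samples)
    grid150 = _resample_xy(samples, map_dims)
    mins = np.nanmin(grid150, axis=2)
    mins = np.where(np.isfinite(mins), np.maximum(mins, 0.0), np.nan)
    return fld, MinO2Map(mins, eye_id=str(stack.meta.get("eye_id", "")), timepoint=str(stack.meta.get("timepoint", "")))


def thinning_map(
    stack_t0: LayerSurfaceStack,
    stack_t1: LayerSurfaceStack,
    reg: RegistrationResult | None = None,
    map_dims: tuple[int, int] = MAP_DIMS,
) -> ThinningMap:
    """Δ(ONL+OPL thickness) = T1 − T0 on the registered grid, resampled to
    the output map dimensions (negative values = thinning)."""
    t0 = SurfaceRaster(stack_t0.onl_opl_thickness, stack_t0.spacing, stack_t0.origin)
    t1 = SurfaceRaster(stack_t1.onl_opl_thickness, stack_t1.spacing, stack_t1.origin)
    if reg is not None:
        t1 = apply_registration(t1, reg)
    delta = t1.values - t0.values  # NaN propagates where either is invalid
    d = _resample_xy(delta.T, map_dims)  # (x, y) indexing, matching MinO2Map
    return ThinningMap(
        d,
        eye_id=str(stack_t0.meta.get("eye_id", "")),
        low_confidence=bool(reg.low_confidence) if reg is not None else False,
    )
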