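"""Synthetic eyes with known ground truth for end-to-end pipeline testing.

No public OCT dataset accompanies the analysis this package implements, so
every pipeline stage is exercised on generated eyes instead: six ordered
layer-boundary surfaces with smooth low-frequency thickness variation, a
central foveal pit, randomly placed spherical-cap drusen between BrM and
the RPE, and a follow-up time point whose ONL+OPL thinning is generated
from the modeled (or surrogate) hypoxia of the baseline geometry, plus
noise and a known rigid misregistration.

The generator encodes the hypothesis under test as generative truth:
follow-up thinning increases with the oxygen deficit below a threshold
pO2.  Setting the druse-height coupling to zero while keeping the hypoxia
coupling positive reproduces, qualitatively, the observed contrast between
a clear hypoxia-thinning correlation and a near-zero height-thinning
correlation.

Everything is deterministic given (config, seed): per-eye substreams are
spawned as ``default_rng([seed, eye_index])``.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .geometry import BRM_THICKNESS_UM, LayerSurfaceStack
from .patient_pipeline import (
    MAP_DIMS,
    MinO2Map,
    _transform_raster,
    crop_to_window,
    flatten_to_baseline,
    reconstruct_is,
    run_patient_model,
)
from .solver import SolverSettings, analytic_1d_min
from .units_params import ModelParams, conc_to_po2

log = logging.getLogger(__name__)

__all__ = [
    "CohortConfig",
    "SyntheticEye",
    "generate_eye",
    "generate_followup",
    "surrogate_min_o2",
    "simulate_eye",
    "simulate_cohort",
    "write_cohort",
]


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort.

    Lengths in μm.  ``druse_diameter_median``/``sigma`` parameterize a
    log-normal diameter distribution; cap height is ``druse_height_ratio``
    times the diameter.  ``hypoxia_sensitivity_beta`` is the generated
    thinning (μm) per mmHg of oxygen deficit below ``p_threshold``;
    ``height_coupling_gamma`` is thinning per μm of druse height (zero to
    emulate the observed lack of a height effect).
    """

    n_eyes: int = 6
    extent_um: float = 6000.0
    spacing_um: float = 40.0
    druse_count_mean: float = 8.0
    druse_diameter_median: float = 150.0
    druse_diameter_sigma: float = 0.4
    druse_height_ratio: float = 0.15
    pit_depth: float = 20.0
    pit_radius: float = 300.0
    thinning_base: float = 0.0
    hypoxia_sensitivity_beta: float = 0.2
    p_threshold: float = 10.0
    height_coupling_gamma: float = 0.0
    noise_sd: float = 2.0
    misreg_dx: float = 80.0
    misreg_dy: float = -40.0
    misreg_rot: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in (
            "extent_um",
            "spacing_um",
            "druse_diameter_median",
            "druse_diameter_sigma",
            "druse_height_ratio",
            "pit_radius",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticEye:
    stack_t0: LayerSurfaceStack
    stack_t1: LayerSurfaceStack | None
    truth: dict = field(default_factory=dict)


def _smooth_field(rng: np.random.Generator, shape, sigma_px: float, amplitude: float) -> np.ndarray:
    """Low-frequency Gaussian random field with ~unit-amplitude scaling."""
    white = rng.standard_normal(shape)
    f = ndimage.gaussian_filter(white, sigma_px, mode="reflect")
    s = f.std()
    return amplitude * f / s if s > 0 else np.zeros(shape)


def generate_eye(config: CohortConfig, eye_index: int, params: ModelParams | None = None) -> SyntheticEye:
    """Baseline stack for one eye; the follow-up stack is attached later by
    :func:`generate_followup` once a hypoxia map exists."""
    params = params or ModelParams()
    rng = np.random.default_rng([config.seed, eye_index])
    n = int(round(config.extent_um / config.spacing_um))
    sp = config.spacing_um
    xs = (np.arange(n) + 0.5) * sp
    X, Y = np.meshgrid(xs, xs)  # (ny, nx)

    # gently tilted, gently undulating basal surface
    tilt = rng.uniform(-0.004, 0.004, size=2)
    z0 = 20.0 + tilt[0] * X + tilt[1] * Y + _smooth_field(rng, (n, n), 25.0 / (sp / 40), 4.0)

    # drusen: spherical caps with bounded-overlap rejection sampling
    n_drusen = int(rng.poisson(config.druse_count_mean))
    margin = 0.15 * config.extent_um
    drusen = []
    h_druse = np.zeros((n, n))
    for _ in range(n_drusen):
        for _attempt in range(20):
            cx, cy = rng.uniform(margin, config.extent_um - margin, size=2)
            d = float(
                config.druse_diameter_median * np.exp(rng.normal(0.0, config.druse_diameter_sigma))
            )
            if all(np.hypot(cx - e["cx"], cy - e["cy"]) > 0.6 * (d + e["d"]) / 2 for e in drusen):
                break
        else:
            raise RuntimeError("could not place druse within packing limit")
        h = config.druse_height_ratio * d
        drusen.append({"cx": cx, "cy": cy, "d": d, "h": h})
        r = np.hypot(X - cx, Y - cy)
        a = d / 2.0
        R = (a * a + h * h) / (2 * h)
        cap = np.where(r <= a, np.sqrt(np.maximum(R * R - r * r, 0.0)) - (R - h), 0.0)
        h_druse = np.maximum(h_druse, cap)

    # foveal pit carved out of the ONL+OPL near the center
    pit_cx, pit_cy = config.extent_um / 2 + rng.uniform(-2 * sp, 2 * sp, size=2)
    r_pit = np.hypot(X - pit_cx, Y - pit_cy)
    pit = config.pit_depth * np.exp(-0.5 * (r_pit / config.pit_radius) ** 2)

    t_onl = params.height_onl_opl * (1.0 + _smooth_field(rng, (n, n), 20.0 / (sp / 40), 0.05)) - pit
    t_onl = np.maximum(t_onl, 1.0)
    t_is = params.height_is * t_onl / t_onl.max()

    z1 = z0 + BRM_THICKNESS_UM
    z2 = z1 + h_druse
    z3 = z0 + h_druse + params.height_sub_is
    z4 = z3 + t_is
    z5 = z4 + t_onl
    stack = LayerSurfaceStack(
        np.stack([z0, z1, z2, z3, z4, z5]),
        sp,
        (0.0, 0.0),
        meta={"eye_id": f"eye{eye_index:03d}", "timepoint": "t0"},
    )
    truth = {
        "pit_center_xy": (float(pit_cx), float(pit_cy)),
        "drusen": drusen,
        "druse_height_field": h_druse,
        "misregistration": {
            "dx": config.misreg_dx,
            "dy": config.misreg_dy,
            "rot": config.misreg_rot,
        },
    }
    return SyntheticEye(stack_t0=stack, stack_t1=None, truth=truth)


def surrogate_min_o2(
    stack: LayerSurfaceStack, params: ModelParams, lateral_sigma_um: float = 40.0
) -> np.ndarray:
    """Solver-independent hypoxia surrogate on the stack grid (mmHg).

    Evaluates the 1D laminar minimum with the local druse height added to
    the passive path, smoothed laterally over a diffusion-scale kernel and
    clamped at zero.  Used for pipeline tests that must not depend on the
    solver, never as a replacement for it.
    """
    h = np.where(stack.mask, stack.druse_height, 0.0)
    h_s = ndimage.gaussian_filter(h, lateral_sigma_um / stack.spacing)
    flat = np.unique(np.round(h_s, 3))
    lut = {v: conc_to_po2(max(analytic_1d_min(params, float(v))[1], 0.0), params) for v in flat}
    out = np.vectorize(lambda v: lut[v])(np.round(h_s, 3))
    return np.where(stack.mask, out, np.nan)


def _min_o2_on_full_grid(
    eye: SyntheticEye, min_o2: MinO2Map, crop: LayerSurfaceStack, params: ModelParams
) -> np.ndarray:
    """Paste a cropped-window minimum-pO2 map back onto the full eye grid,
    filling outside the window with the healthy laminar minimum."""
    stack = eye.stack_t0
    ny, nx = stack.shape
    healthy = conc_to_po2(max(analytic_1d_min(params)[1], 0.0), params)
    full = np.full((ny, nx), healthy)
    n_win = crop.shape[0]
    x0 = int(round((crop.origin[0] - stack.origin[0]) / stack.spacing))
    y0 = int(round((crop.origin[1] - stack.origin[1]) / stack.spacing))
    ix = np.minimum((np.arange(n_win) * min_o2.values.shape[0]) // n_win, min_o2.values.shape[0] - 1)
    vals = min_o2.values[np.ix_(ix, ix)]  # (x, y) indexing
    patch = vals.T  # back to (iy, ix)
    patch = np.where(np.isfinite(patch), patch, healthy)
    full[y0 : y0 + n_win, x0 : x0 + n_win] = patch
    return full


def generate_followup(
    eye: SyntheticEye,
    min_o2: MinO2Map,
    crop: LayerSurfaceStack,
    config: CohortConfig,
) -> LayerSurfaceStack:
    """Attach the follow-up stack: hypoxia-coupled ONL+OPL thinning plus
    noise, then the configured rigid misregistration.

    Δ(ONL+OPL)(x, y) = base − β·max(0, p_thresh − minO2) + γ·h_druse + ε.
    """
    params = ModelParams()
    rng = np.random.default_rng([config.seed, 7919, int(eye.truth.get("_index", 0))])
    stack = eye.stack_t0
    o2 = _min_o2_on_full_grid(eye, min_o2, crop, params)
    deficit = np.maximum(0.0, config.p_threshold - o2)
    delta_clean = (
        config.thinning_base
        - config.hypoxia_sensitivity_beta * deficit
        + config.height_coupling_gamma * eye.truth["druse_height_field"]
    )
    noise = rng.normal(0.0, config.noise_sd, size=stack.shape) if config.noise_sd > 0 else 0.0
    delta = delta_clean + noise

    t1 = stack.copy()
    new_z5 = t1.surfaces[5] + delta
    clipped = new_z5 < t1.surfaces[4]
    if clipped.any():
        log.warning("thinning clipped at zero thickness in %d pixels", int(clipped.sum()))
    t1.surfaces[5] = np.maximum(new_z5, t1.surfaces[4])

    sp = stack.spacing
    shift_px = (int(round(config.misreg_dx / sp)), int(round(config.misreg_dy / sp)))
    surfaces = np.stack(
        [
            _transform_raster(np.where(t1.mask, s, np.nan), config.misreg_rot, shift_px)
            for s in t1.surfaces
        ]
    )
    mask = np.isfinite(surfaces).all(axis=0)
    t1 = LayerSurfaceStack(
        np.where(mask, surfaces, 0.0),
        sp,
        stack.origin,
        mask,
        {**stack.meta, "timepoint": "t1"},
    )
    eye.stack_t1 = t1
    eye.truth["delta_clean"] = delta_clean
    eye.truth["delta_applied"] = np.asarray(delta)
    eye.truth["min_o2_full"] = o2
    return t1


def simulate_eye(
    config: CohortConfig,
    eye_index: int,
    params: ModelParams | None = None,
    settings: SolverSettings | None = None,
    use_surrogate: bool = False,
    window_um: float = 3000.0,
    spacing_z: float = 2.0,
    map_dims: tuple[int, int] = MAP_DIMS,
) -> tuple[SyntheticEye, MinO2Map]:
    """Generate a complete two-time-point eye, running the oxygen model (or
    the analytic surrogate) on the baseline crop to drive the follow-up."""
    params = params or ModelParams()
    eye = generate_eye(config, eye_index, params)
    eye.truth["_index"] = eye_index
    crop = crop_to_window(eye.stack_t0, window_um)
    if use_surrogate:
        sur = surrogate_min_o2(crop, params)
        from .patient_pipeline import _resample_xy

        vals = _resample_xy(sur.T, map_dims)
        min_map = MinO2Map(np.maximum(vals, 0.0), eye_id=eye.stack_t0.meta["eye_id"], timepoint="t0")
    else:
        prepared = reconstruct_is(flatten_to_baseline(crop))
        _, min_map = run_patient_model(prepared, params, settings, spacing_z, map_dims)
    generate_followup(eye, min_map, crop, config)
    return eye, min_map


def simulate_cohort(config: CohortConfig, **kwargs) -> list[tuple[SyntheticEye, MinO2Map]]:
    return [simulate_eye(config, i, **kwargs) for i in range(config.n_eyes)]


def write_cohort(
    cohort: list[tuple[SyntheticEye, MinO2Map]],
    directory: str | Path,
    blind: bool = False,
    overwrite: bool = False,
) -> list[Path]:
    """Write per-eye manifests and rasters consumable by the pipeline.

    Truth is kept in a sibling ``truth/`` tree (omitted when ``blind``) so
    blind re-analyses remain possible.
    """
    from .patient_pipeline import write_surface_stack
    from .raster import SurfaceRaster, write_ascii_grid

    directory = Path(directory)
    manifests = []
    for eye, min_map in cohort:
        eid = eye.stack_t0.meta["eye_id"]
        eye_dir = directory / eid
        if eye_dir.exists() and not overwrite:
            raise FileExistsError(f"{eye_dir} exists (pass overwrite=True)")
        manifests.append(write_surface_stack(eye.stack_t0, eye_dir / "t0", overwrite=overwrite))
        if eye.stack_t1 is not None:
            write_surface_stack(eye.stack_t1, eye_dir / "t1", overwrite=overwrite)
        if not blind:
            tdir = directory / "truth" / eid
            tdir.mkdir(parents=True, exist_ok=True)
            sp = eye.stack_t0.spacing
            write_ascii_grid(tdir / "druse_height.asc", SurfaceRaster(eye.truth["druse_height_field"], sp))
            if "delta_clean" in eye.truth:
                write_ascii_grid(tdir / "delta_clean.asc", SurfaceRaster(eye.truth["delta_clean"], sp))
            scalars = {
                "pit_center_xy": eye.truth["pit_center_xy"],
                "misregistration": eye.truth["misregistration"],
            }
            (tdir / "truth.json").write_text(json.dumps(scalars, indent=1))
            with open(tdir / "drusen.csv", "w", newline="") as fh:
                w = csv.DictWriter(fh, fieldnames=["cx", "cy", "d", "h"])
                w.writeheader()
                w.writerows(eye.truth["drusen"])
    return manifests
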