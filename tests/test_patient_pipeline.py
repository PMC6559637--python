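import numpy as np
import pytest

from retoxsim import (
    ModelParams,
    read_surface_stack,
    register_timepoints,
    render_generic_stack,
    run_patient_model,
    thinning_map,
    write_surface_stack,
)
from retoxsim.geometry import LayerSurfaceStack
from retoxsim.patient_pipeline import (
    RegistrationResult,
    _transform_raster,
    crop_to_window,
    find_fovea,
    flatten_to_baseline,
    reconstruct_is,
)
from retoxsim.raster import SurfaceRaster, read_ascii_grid, write_ascii_grid
from retoxsim.synthetic_cohort import generate_eye


class TestRasterIO:
    def test_ascii_grid_round_trip(self, tmp_path, rng):
        v = rng.normal(50, 5, size=(12, 9))
        v[0, 0] = np.nan
        r = SurfaceRaster(v, spacing=40.0, origin=(100.0, 200.0))
        write_ascii_grid(tmp_path / "a.asc", r)
        back = read_ascii_grid(tmp_path / "a.asc")
        assert back.spacing == 40.0
        assert back.origin == (100.0, 200.0)
        assert not back.mask[0, 0]
        np.testing.assert_allclose(back.values[back.mask], v[back.mask], rtol=1e-6)


class TestStackIO:
    def test_write_read_round_trip(self, tmp_path, params):
        stack = render_generic_stack(params, 10, 10, 40.0)
        stack.meta["eye_id"] = "eyeX"
        m = write_surface_stack(stack, tmp_path / "eyeX")
        back = read_surface_stack(m)
        np.testing.assert_allclose(back.surfaces, stack.surfaces, rtol=1e-6)
        assert back.meta["eye_id"] == "eyeX"

    def test_mismatched_spacing_rejected(self, tmp_path, params):
        stack = render_generic_stack(params, 10, 10, 40.0)
        m = write_surface_stack(stack, tmp_path / "bad")
        # rewrite one surface at a different cellsize
        r = read_ascii_grid(tmp_path / "bad" / "z3_rpe_os_top.asc")
        r.spacing = 60.0
        write_ascii_grid(tmp_path / "bad" / "z3_rpe_os_top.asc", r)
        with pytest.raises(ValueError, match="z3"):
            read_surface_stack(m)

    def test_rare_ordering_violations_repaired(self, tmp_path, params):
        stack = render_generic_stack(params, 10, 10, 40.0)
        stack.surfaces[3, 5, 5], stack.surfaces[4, 5, 5] = (
            stack.surfaces[4, 5, 5],
            stack.surfaces[3, 5, 5],
        )
        d = tmp_path / "rep"
        d.mkdir()
        for name, surf in zip(
            ["z0_brm_base", "z1_brm_top", "z2_druse_top", "z3_rpe_os_top", "z4_is_top", "z5_onl_opl_top"],
            stack.surfaces,
        ):
            write_ascii_grid(d / f"{name}.asc", SurfaceRaster(surf, 40.0))
        import json

        (d / "manifest.json").write_text(
            json.dumps(
                {
                    "surfaces_basal_to_apical": [
                        "z0_brm_base.asc", "z1_brm_top.asc", "z2_druse_top.asc",
                        "z3_rpe_os_top.asc", "z4_is_top.asc", "z5_onl_opl_top.asc",
                    ],
                    "spacing_um": 40.0,
                }
            )
        )
        back = read_surface_stack(d / "manifest.json")
        back.validate_ordering()

    def test_synthetic_eye_passes_validation(self, small_cohort_config, tmp_path):
        eye = generate_eye(small_cohort_config, 0)
        m = write_surface_stack(eye.stack_t0, tmp_path / "syn")
        back = read_surface_stack(m)
        back.validate_ordering()


class TestRegistration:
    def _thickness_map(self, cfg, idx=0):
        eye = generate_eye(cfg, idx)
        s = eye.stack_t0
        return SurfaceRaster(s.sub_rpe_thickness, s.spacing, s.origin)

    def test_identity_for_identical_maps(self, small_cohort_config):
        a = self._thickness_map(small_cohort_config)
        reg = register_timepoints(a, a, translation_range=150.0)
        assert reg.rotation == 0.0
        assert reg.translation == (0.0, 0.0)
        assert reg.pearson_r_at_optimum == pytest.approx(1.0, abs=1e-12)

    def test_known_whole_pixel_shift_recovered(self, small_cohort_config):
        a = self._thickness_map(small_cohort_config)
        shifted = SurfaceRaster(
            _transform_raster(a.values, 0.0, (2, 0)), a.spacing, a.origin
        )  # +2 px in x = +100 μm
        reg = register_timepoints(a, shifted, translation_range=200.0)
        assert reg.rotation == 0.0
        assert reg.translation == (-100.0, 0.0)
        assert reg.pearson_r_at_optimum > 0.999

    def test_uncorrelated_noise_flagged_low_confidence(self, rng):
        a = SurfaceRaster(rng.normal(60, 5, (40, 40)), 50.0)
        b = SurfaceRaster(rng.normal(60, 5, (40, 40)), 50.0)
        reg = register_timepoints(a, b, rotation_range=1.0, translation_range=100.0)
        assert reg.low_confidence
        assert abs(reg.pearson_r_at_optimum) < 0.5


class TestCropAndFlatten:
    def test_pit_detected_within_one_pixel(self, small_cohort_config):
        eye = generate_eye(small_cohort_config, 1)
        iy, ix = find_fovea(eye.stack_t0)
        sp = eye.stack_t0.spacing
        cx, cy = eye.truth["pit_center_xy"]
        assert abs((ix + 0.5) * sp - cx) <= 2.1 * sp
        assert abs((iy + 0.5) * sp - cy) <= 2.1 * sp

    def test_crop_centered_and_sized(self, small_cohort_config):
        eye = generate_eye(small_cohort_config, 0)
        crop = crop_to_window(eye.stack_t0, window_um=1500.0)
        assert crop.shape == (30, 30)

    def test_fovea_near_edge_rejected(self, params):
        stack = render_generic_stack(params, 20, 20, 50.0)
        stack.surfaces[5, 1, 1] -= 30.0  # artificial pit near the corner
        with pytest.raises(ValueError, match="window"):
            crop_to_window(stack, window_um=900.0)

    def test_flatten_zeroes_base_and_preserves_thickness(self, small_cohort_config):
        eye = generate_eye(small_cohort_config, 2)
        flat = flatten_to_baseline(eye.stack_t0)
        assert np.abs(flat.surfaces[0][flat.mask]).max() < 1e-9
        np.testing.assert_allclose(
            flat.onl_opl_thickness[flat.mask],
            eye.stack_t0.onl_opl_thickness[eye.stack_t0.mask],
            atol=1e-9,
        )

    def test_tilt_removed_by_flattening(self, params):
        n, sp = 16, 50.0
        xs = (np.arange(n) + 0.5) * sp
        tilt = 0.01 * xs[None, :] + 0.005 * xs[:, None]
        tilted = render_generic_stack(params, n, n, sp, base_height=tilt)
        ref = render_generic_stack(params, n, n, sp)
        flat = flatten_to_baseline(tilted)
        np.testing.assert_allclose(
            flat.surfaces, flatten_to_baseline(ref).surfaces, atol=1e-9
        )


class TestReconstructIs:
    def test_linear_scaling_of_is_thickness(self, params):
        stack = render_generic_stack(params, 10, 10, 50.0)
        t = stack.onl_opl_thickness.copy()
        stack.surfaces[5] = stack.surfaces[4] + t * np.linspace(0.5, 1.0, 10)[None, :]
        out = reconstruct_is(stack, is_max_um=25.0)
        tt = out.onl_opl_thickness
        is_t = out.thickness(3, 4)
        np.testing.assert_allclose(is_t, 25.0 * tt / np.nanmax(tt), atol=1e-9)

    def test_zero_onl_everywhere_rejected(self, params):
        stack = render_generic_stack(params, 8, 8, 50.0)
        stack.surfaces[5] = stack.surfaces[4]
        with pytest.raises(ValueError):
            reconstruct_is(stack)


class TestPatientModel:
    def test_flat_stack_recovers_generic_minimum(self, params, settings, generic_field):
        stack = render_generic_stack(params, 24, 24, 50.0)
        stack.meta["z_window_um"] = 400.0
        prepared = reconstruct_is(flatten_to_baseline(stack))
        _, mm = run_patient_model(prepared, params, settings, spacing_z=1.0)
        assert mm.values.shape == (150, 150)
        interior = mm.values[30:-30, 30:-30]
        assert np.nanmedian(interior) == pytest.approx(generic_field.min_po2(), rel=0.05)

    def test_unflattened_stack_rejected(self, params, settings):
        stack = render_generic_stack(params, 12, 12, 50.0, base_height=10.0)
        with pytest.raises(ValueError, match="flatten"):
            run_patient_model(reconstruct_is(stack), params, settings)


class TestThinningMap:
    def test_identical_stacks_give_zero(self, params):
        s = render_generic_stack(params, 30, 30, 50.0)
        tm = thinning_map(s, s)
        assert np.nanmax(np.abs(tm.values)) < 1e-9

    def test_uniform_thinning_recovered(self, params):
        s0 = render_generic_stack(params, 30, 30, 50.0)
        s1 = s0.copy()
        s1.surfaces[5] -= 3.0
        tm = thinning_map(s0, s1)
        assert np.nanmean(tm.values) == pytest.approx(-3.0, abs=1e-9)

    def test_registration_residual_below_1um_rms(self, small_cohort_config, params):
        # shift a smooth stack by whole pixels, register, and check the
        # end-to-end thinning residual
        eye = generate_eye(small_cohort_config, 3)
        s0 = eye.stack_t0
        shifted = np.stack([_transform_raster(s, 0.0, (2, -1)) for s in s0.surfaces])
        mask = np.isfinite(shifted).all(axis=0)
        s1 = LayerSurfaceStack(np.where(mask, shifted, 0.0), s0.spacing, s0.origin, mask)
        reg = register_timepoints(
            SurfaceRaster(s0.sub_rpe_thickness, s0.spacing),
            SurfaceRaster(s1.sub_rpe_thickness, s1.spacing),
            translation_range=200.0,
        )
        from retoxsim.patient_pipeline import align_stack

        s1_aligned = align_stack(s1, reg)
        tm = thinning_map(s0, s1_aligned)
        resid = tm.values[np.isfinite(tm.values)]
        assert np.sqrt(np.mean(resid**2)) < 1.0
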