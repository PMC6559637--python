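import numpy as np
import pytest

from retoxsim import (
    AxiGrid,
    DruseSpec,
    Grid3D,
    Label,
    ModelParams,
    SolverSettings,
    analytic_1d_min,
    analytic_1d_profile,
    build_generic_domains,
    conc_to_po2,
    insert_druse,
    mass_balance,
    min_po2_by_column,
    render_generic_stack,
    solve_steady_state,
    surfaces_to_domains,
)

# frozen closed-form values, evaluated by hand from the piecewise solution
C_AT_55UM = 0.0214994923857868
C_MIN_1D = 0.00399361880916449
Z_MIN_1D = 76.58783783783784


class TestAnalyticOracle:
    def test_frozen_piecewise_values(self, params):
        assert analytic_1d_profile(params, 0.0) == pytest.approx(0.1107, rel=1e-12)
        assert analytic_1d_profile(params, 55.0) == pytest.approx(C_AT_55UM, rel=1e-12)
        z, c, anoxic = analytic_1d_min(params)
        assert z == pytest.approx(Z_MIN_1D, rel=1e-9)
        assert c == pytest.approx(C_MIN_1D, rel=1e-9)
        assert not anoxic

    def test_no_sink_no_flux_profile_is_constant(self):
        p = ModelParams(consumption_rate_is=1e-30, retinal_flux=1e-30)
        z = np.linspace(0, 125, 26)
        assert analytic_1d_profile(p, z) == pytest.approx(0.1107, rel=1e-9)

    def test_extra_passive_path_flags_anoxia(self, params):
        _, _, anoxic = analytic_1d_min(params, extra_passive_um=40.0)
        assert anoxic


class TestGenericSolve:
    def test_minimum_in_inner_segments(self, generic_field):
        p = generic_field.po2()
        kmin = np.nanargmin(p[0])
        assert Label(generic_field.domains.labels[0, kmin]) == Label.IS
        assert generic_field.min_po2() == pytest.approx(
            conc_to_po2(C_MIN_1D, generic_field.params_used), abs=0.05
        )

    def test_matches_1d_closed_form_within_1pct(self, params, generic_field):
        zc = generic_field.grid.z_centers
        ana = analytic_1d_profile(params, zc)
        num = generic_field.concentration[150]
        assert np.nanmax(np.abs(num - ana) / ana) < 0.01

    def test_grid_halving_reduces_error_at_scheme_order(self, params, settings, generic_field):
        zc = generic_field.grid.z_centers
        err1 = np.nanmax(
            np.abs(generic_field.concentration[150] - analytic_1d_profile(params, zc))
            / analytic_1d_profile(params, zc)
        )
        grid = AxiGrid(n_r=120, n_z=250, spacing=0.5)
        f2 = solve_steady_state(build_generic_domains(params, grid), params, settings)
        zc2 = grid.z_centers
        err2 = np.nanmax(
            np.abs(f2.concentration[60] - analytic_1d_profile(params, zc2))
            / analytic_1d_profile(params, zc2)
        )
        assert err1 < 0.01
        assert err2 < err1 / 3  # consistent with a second-order scheme

    def test_no_source_no_sink_gives_uniform_dirichlet_value(self, settings):
        p = ModelParams(consumption_rate_is=1e-30, retinal_flux=1e-30)
        grid = AxiGrid(n_r=20, n_z=130, spacing=1.0)
        f = solve_steady_state(build_generic_domains(p, grid), p, settings)
        c = f.concentration[f.domains.tissue_mask]
        assert c == pytest.approx(0.1107, rel=1e-9)

    def test_nonnegative_everywhere_and_no_clamping_when_healthy(self, generic_field):
        c = generic_field.concentration
        assert np.nanmin(c) >= 0
        assert not generic_field.clamped_mask.any()
        assert generic_field.active_consumption_mask.sum() == (
            generic_field.domains.labels == Label.IS
        ).sum()


class TestMassBalance:
    def test_converged_solve_conserves_flux(self, generic_field):
        b = mass_balance(generic_field)
        assert b.relative_imbalance < 1e-3
        assert b.influx_retinal / b.total_consumption == pytest.approx(0.1364865, abs=1e-4)

    def test_zero_everything_balances_trivially(self, settings):
        p = ModelParams(consumption_rate_is=1e-30, retinal_flux=1e-30)
        grid = AxiGrid(n_r=20, n_z=130, spacing=1.0)
        f = solve_steady_state(build_generic_domains(p, grid), p, settings)
        b = mass_balance(f)
        assert abs(b.total_consumption) < 1e-20
        assert b.relative_imbalance < 1e-6

    def test_anoxic_solve_still_conserves(self, params, settings):
        grid = AxiGrid(n_r=400, n_z=165, spacing=1.0)
        f = solve_steady_state(
            insert_druse(params, DruseSpec("hemisphere", 80.0), grid), params, settings
        )
        assert f.clamped_mask.any()  # anoxic core present
        assert mass_balance(f).relative_imbalance < 1e-3


class TestActiveSet:
    def test_clamped_cells_zero_active_cells_positive(self, params, settings):
        grid = AxiGrid(n_r=400, n_z=165, spacing=1.0)
        f = solve_steady_state(
            insert_druse(params, DruseSpec("hemisphere", 80.0), grid), params, settings
        )
        assert (f.concentration[f.clamped_mask] == 0).all()
        is_active = f.active_consumption_mask
        assert (f.concentration[is_active] > 0).all()

    def test_monotone_in_consumption_rate(self, settings):
        grid = AxiGrid(n_r=20, n_z=130, spacing=1.0)
        mins = []
        for q in (0.10, 0.148, 0.20):
            p = ModelParams(consumption_rate_is=q)
            f = solve_steady_state(build_generic_domains(p, grid), p, settings)
            mins.append(f.min_po2())
        assert mins[0] > mins[1] > mins[2]

    def test_monotone_in_retinal_flux(self, settings):
        grid = AxiGrid(n_r=20, n_z=130, spacing=1.0)
        fields = []
        for j in (2e-7, 5.05e-7, 8e-7):
            p = ModelParams(retinal_flux=j)
            f = solve_steady_state(build_generic_domains(p, grid), p, settings)
            fields.append(f.concentration)
        assert np.all(np.nan_to_num(fields[1] - fields[0]) >= -1e-12)
        assert np.all(np.nan_to_num(fields[2] - fields[1]) >= -1e-12)


class TestMinPo2ByColumn:
    def test_equals_brute_force_column_scan(self, generic_field):
        m = min_po2_by_column(generic_field)
        p = generic_field.po2()
        brute = np.nanmin(p, axis=-1)
        assert m == pytest.approx(brute, rel=1e-12)

    def test_uniform_field_maps_to_80(self, settings):
        p = ModelParams(consumption_rate_is=1e-30, retinal_flux=1e-30)
        grid = AxiGrid(n_r=10, n_z=130, spacing=1.0)
        f = solve_steady_state(build_generic_domains(p, grid), p, settings)
        assert min_po2_by_column(f) == pytest.approx(80.0, rel=1e-9)


class TestAxi3DAgreement:
    def test_same_druse_solved_both_ways(self, params, settings):
        d = 40.0
        n, sp = 50, 4.0
        c = n * sp / 2
        stack = render_generic_stack(
            params, n, n, sp, drusen=[DruseSpec("hemisphere", d, center_xy=(c, c))]
        )
        f3 = solve_steady_state(
            surfaces_to_domains(stack, Grid3D(n, n, 73, sp, 2.0)), params, settings
        )
        axi = solve_steady_state(
            insert_druse(params, DruseSpec("hemisphere", d), AxiGrid(75, 73, 2.0, spacing_r=4.0)),
            params,
            settings,
        )
        m3 = np.nanmin(f3.po2())
        ma = np.nanmin(axi.po2())
        assert m3 == pytest.approx(ma, rel=0.05)
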