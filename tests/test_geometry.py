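import numpy as np
import pytest
from hypothesis import given, settings as hsettings, strategies as st

from retoxsim import (
    AxiGrid,
    DruseSpec,
    Grid3D,
    Label,
    build_generic_domains,
    druse_height_profile,
    insert_druse,
    render_generic_stack,
    surfaces_to_domains,
)
from retoxsim.geometry import LayerSurfaceStack


def label_at(field, r_um, z_um):
    g = field.grid
    i = int(r_um / g.dr)
    k = int(z_um / g.dz)
    return Label(field.labels[i, k])


class TestGenericDomains:
    def test_layer_boundaries_follow_nominal_heights(self, params):
        grid = AxiGrid(n_r=10, n_z=140, spacing=1.0)
        f = build_generic_domains(params, grid)
        assert label_at(f, 5, 60.5) == Label.IS  # 55 < z < 80
        assert label_at(f, 5, 30.5) == Label.RPE_OS
        assert label_at(f, 5, 100.5) == Label.ONL_OPL
        assert label_at(f, 5, 130.5) == Label.OUTSIDE
        # tissue column is exactly 125 μm everywhere
        assert (f.tissue_mask.sum(axis=1) == 125).all()

    def test_every_cell_has_exactly_one_label(self, params):
        grid = AxiGrid(n_r=8, n_z=130, spacing=1.0)
        f = build_generic_domains(params, grid)
        assert set(np.unique(f.labels)) <= {int(l) for l in Label}

    def test_short_grid_rejected(self, params):
        with pytest.raises(ValueError, match="z-extent"):
            build_generic_domains(params, AxiGrid(n_r=8, n_z=100, spacing=1.0))


class TestDruseProfile:
    def test_hemisphere_apex_and_rim(self):
        h = DruseSpec("hemisphere", 64.0)
        assert druse_height_profile(h, 0.0) == pytest.approx(32.0)
        assert druse_height_profile(h, 32.0) == pytest.approx(0.0)
        assert druse_height_profile(h, 100.0) == 0.0

    def test_cylinder_flat_top(self):
        c = DruseSpec("cylinder", 82.0, height=20.0)
        assert druse_height_profile(c, 10.0) == 20.0
        assert druse_height_profile(c, 41.0) == 20.0
        assert druse_height_profile(c, 41.1) == 0.0

    @hsettings(derandomize=True, max_examples=30)
    @given(
        d=st.floats(min_value=1, max_value=500),
        r=st.floats(min_value=0, max_value=600),
    )
    def test_hemisphere_profile_bounded_by_radius(self, d, r):
        h = druse_height_profile(DruseSpec("hemisphere", d), r)
        assert 0 <= h <= d / 2 + 1e-9


class TestInsertDruse:
    def test_layers_displaced_by_local_druse_height(self, params):
        grid = AxiGrid(n_r=200, n_z=170, spacing=1.0)
        f = insert_druse(params, DruseSpec("hemisphere", 64.0), grid)
        # on the axis the IS lower boundary moves from 55 to ~87 μm
        assert label_at(f, 0.5, 86.5) == Label.RPE_OS
        assert label_at(f, 0.5, 87.5) == Label.IS
        assert label_at(f, 0.5, 20.5) == Label.DRUSEN  # druse sits just above BrM

    def test_cylinder_rigid_shift_of_top_surface(self, params):
        grid = AxiGrid(n_r=300, n_z=150, spacing=1.0)
        f = insert_druse(params, DruseSpec("cylinder", 82.0, height=20.0), grid)
        # above the druse the column ends at 145 μm, beyond the rim at 125 μm
        assert f.tissue_mask[0].sum() == 145
        assert f.tissue_mask[-1].sum() == 125

    def test_zero_diameter_limit_recovers_generic_field(self, params):
        grid = AxiGrid(n_r=50, n_z=130, spacing=1.0)
        tiny = insert_druse(params, DruseSpec("cylinder", 1e-9, height=1e-9), grid)
        flat = build_generic_domains(params, grid)
        assert (tiny.labels == flat.labels).all()

    def test_layer_thickness_conserved_in_every_column(self, params):
        grid = AxiGrid(n_r=100, n_z=170, spacing=1.0)
        f = insert_druse(params, DruseSpec("hemisphere", 80.0), grid)
        for lab, nominal in [(Label.RPE_OS, 51), (Label.IS, 25), (Label.ONL_OPL, 45)]:
            per_col = (f.labels == lab).sum(axis=1)
            assert np.abs(per_col - nominal).max() <= 1

    def test_too_tall_druse_rejected(self, params):
        grid = AxiGrid(n_r=100, n_z=130, spacing=1.0)
        with pytest.raises(ValueError):
            insert_druse(params, DruseSpec("hemisphere", 100.0), grid)


class TestSurfacesToDomains:
    def test_flat_stack_reproduces_generic_field(self, params):
        stack = render_generic_stack(params, 8, 8, 10.0)
        grid = Grid3D(8, 8, 130, 10.0, 1.0)
        f3 = surfaces_to_domains(stack, grid)
        flat = build_generic_domains(params, AxiGrid(8, 130, 1.0))
        assert (f3.labels[0, 0] == flat.labels[0]).all()

    def test_zero_thickness_drusen_layer_produces_no_cells(self, params):
        stack = render_generic_stack(params, 8, 8, 10.0)
        f3 = surfaces_to_domains(stack, Grid3D(8, 8, 130, 10.0, 1.0))
        assert not (f3.labels == Label.DRUSEN).any()

    def test_hemispherical_bump_matches_axisymmetric_insert(self, params):
        n, sp = 40, 4.0
        c = n * sp / 2
        stack = render_generic_stack(
            params, n, n, sp, drusen=[DruseSpec("hemisphere", 64.0, center_xy=(c, c))]
        )
        f3 = surfaces_to_domains(stack, Grid3D(n, n, 160, sp, 1.0))
        axi = insert_druse(params, DruseSpec("hemisphere", 64.0), AxiGrid(60, 160, 1.0, spacing_r=sp))
        # compare the column through the druse center against the axis column
        ic = int(c / sp)
        col3d = f3.labels[ic, ic]
        col_axi = axi.labels[0]
        assert (col3d != col_axi).mean() < 0.05  # within one-cell quantization

    def test_ordering_violation_rejected(self, params):
        stack = render_generic_stack(params, 8, 8, 10.0)
        bad = stack.surfaces.copy()
        bad[3, 4, 4] = bad[5, 4, 4] + 10.0
        with pytest.raises(ValueError, match="ordering"):
            surfaces_to_domains(
                LayerSurfaceStack(bad, 10.0), Grid3D(8, 8, 130, 10.0, 1.0)
            )

    def test_nodata_columns_are_outside(self, params):
        stack = render_generic_stack(params, 8, 8, 10.0)
        stack.mask[0, :] = False
        f3 = surfaces_to_domains(stack, Grid3D(8, 8, 130, 10.0, 1.0))
        assert (f3.labels[:, 0, :] == Label.OUTSIDE).all()
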