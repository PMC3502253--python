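"""Spill-out activity, local backgrounds and the corrected mean."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hotpvc import (
    PsfModel,
    VoxelGrid,
    as_roi,
    build_shells,
    run_gbpvc,
    run_lbpvc,
    spillout_activity,
)
from hotpvc.analytic import spillout_fraction
from hotpvc.pvc_core import correct_mean, global_background, local_background, local_backgrounds
from tests.conftest import make_sphere_grid


def _roi_from(grid, mask):
    return as_roi(grid, mask)


class TestCorrectMean:
    def test_arithmetic(self):
        g = VoxelGrid(np.full((6, 6, 6), 8.0), (10, 10, 10))  # V_vox = 1 mL
        mask = np.zeros((6, 6, 6), bool)
        mask[1:3, 1:3, 1:3] = False
        mask[0, 0, :] = True  # any 10 mL is fine; use 10 voxels
        mask[0, 1, :4] = True
        roi = _roi_from(g, mask)
        assert roi.v_roi_ml == pytest.approx(10.0)
        res = correct_mean(roi, a_sp=16.0)
        assert res.c_mean_corrected == pytest.approx(9.6)
        assert res.a_roi == pytest.approx(80.0)

    def test_zero_spillout_leaves_mean_unchanged(self):
        g = VoxelGrid(np.full((4, 4, 4), 5.0), (4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        res = correct_mean(_roi_from(g, mask), a_sp=0.0)
        assert res.c_mean_corrected == res.c_mean_uncorrected

    def test_negative_spillout_sign_propagates(self):
        g = VoxelGrid(np.full((4, 4, 4), 8.0), (4, 4, 4))
        mask = np.ones((4, 4, 4), bool)
        roi = _roi_from(g, mask)
        res = correct_mean(roi, a_sp=-roi.c_mean * roi.v_roi_ml / 2.0)
        assert res.c_mean_corrected == pytest.approx(roi.c_mean / 2.0)


class TestSpilloutActivity:
    def test_two_voxel_arithmetic(self):
        vals = np.zeros((8, 8, 8))
        g = VoxelGrid(vals, (4, 4, 4))
        mask = np.zeros((8, 8, 8), bool)
        mask[4, 4, 4] = True
        shells = build_shells(mask, PsfModel(4.0), g.spacing)
        backgrounds = np.zeros((8, 8, 8))
        vals2 = vals.copy()
        spill_idx = np.argwhere(shells.spillout_mask)
        vals2[tuple(spill_idx[0])] = 2.0
        vals2[tuple(spill_idx[1])] = 1.0
        a_sp = spillout_activity(g.with_values(vals2), shells, backgrounds)
        assert a_sp == pytest.approx(0.064 * 3.0)

    def test_zero_when_background_equals_signal(self):
        g = VoxelGrid(np.full((10, 10, 10), 4.2), (4, 4, 4))
        mask = np.zeros((10, 10, 10), bool)
        mask[4:6, 4:6, 4:6] = True
        shells = build_shells(mask, PsfModel(8.0), g.spacing)
        assert spillout_activity(g, shells, np.full((10, 10, 10), 4.2)) == 0.0

    def test_shape_mismatch_rejected(self):
        g = VoxelGrid(np.zeros((6, 6, 6)), (4, 4, 4))
        mask = np.zeros((6, 6, 6), bool)
        mask[3, 3, 3] = True
        shells = build_shells(mask, PsfModel(4.0), g.spacing)
        with pytest.raises(ValueError):
            spillout_activity(g, shells, np.zeros((5, 5, 5)))

    def test_blurred_sphere_spillout_matches_analytic_fraction(self, blurred_sphere40):
        """With the true mask and zero background, A_sp / total activity
        equals the analytic fraction of activity displaced outside the
        sphere (background-free sphere, amplitude 1)."""
        grid, mask = make_sphere_grid(radius_mm=12.0, amplitude=1.0, background=0.0)
        from hotpvc import gaussian_smooth

        blurred = gaussian_smooth(grid, PsfModel(8.0))
        shells = build_shells(mask, PsfModel(8.0), grid.spacing)
        a_sp = spillout_activity(blurred, shells, np.zeros(grid.shape))
        total = grid.values.sum() * grid.voxel_volume_ml
        expected = spillout_fraction(12.0, 8.0)
        # the discrete shell misses the small tail beyond one FWHM and
        # carries voxelization error on a ~12 mm radius mask
        assert a_sp / total == pytest.approx(expected, rel=0.10)


class TestLocalBackground:
    def test_homogeneous_background_everywhere(self):
        g = VoxelGrid(np.full((16, 16, 16), 2.5), (4, 4, 4))
        mask = np.zeros((16, 16, 16), bool)
        mask[7:9, 7:9, 7:9] = True
        shells = build_shells(mask, PsfModel(8.0), g.spacing)
        b_map, n_fallback = local_backgrounds(g, shells)
        assert n_fallback == 0
        np.testing.assert_allclose(b_map[shells.spillout_mask], 2.5)

    def test_single_voxel_matches_convolved_map(self):
        rng = np.random.default_rng(8)
        g = VoxelGrid(rng.uniform(1, 3, (16, 16, 16)), (4, 4, 4))
        mask = np.zeros((16, 16, 16), bool)
        mask[7:9, 7:9, 7:9] = True
        shells = build_shells(mask, PsfModel(8.0), g.spacing)
        b_map, _ = local_backgrounds(g, shells)
        for voxel in map(tuple, np.argwhere(shells.spillout_mask)[::7]):
            value, fallback = local_background(voxel, g, shells)
            assert not fallback
            assert value == pytest.approx(b_map[voxel], rel=1e-12)

    def test_necrotic_cavity_uses_global_fallback(self):
        """A spill-out voxel enclosed by the lesion (central necrosis) has no
        background in range and falls back to the global background mean."""
        x = 4.0 * np.arange(25)
        c = 4.0 * 12
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        r = np.sqrt((X - c) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
        mask = (r <= 12.5) & (r > 2.0)  # shell lesion: centre voxel excluded
        g = VoxelGrid(np.where(mask, 8.0, 1.0), (4, 4, 4))
        shells = build_shells(mask, PsfModel(4.0), g.spacing)
        assert shells.spillout_mask[12, 12, 12]
        value, fallback = local_background((12, 12, 12), g, shells)
        assert fallback
        assert value == pytest.approx(global_background(g, shells))
        _, n_fallback = local_backgrounds(g, shells)
        assert n_fallback >= 1


class TestRunCorrection:
    def test_true_mask_noiseless_recovery_within_1pc(self, blurred_sphere40):
        grid, mask = blurred_sphere40
        roi = _roi_from(grid, mask)
        res = run_lbpvc(grid, roi, psf=PsfModel(8.0))
        assert res.c_mean_corrected == pytest.approx(8.0, rel=0.01)
        assert res.c_mean_uncorrected < 7.2  # substantial uncorrected loss

    def test_flat_background_lbpvc_equals_gbpvc(self, sphere40, blurred_sphere40):
        """On a truly constant background region every local mean equals the
        global mean exactly; with a blurred lesion the residual tail in the
        shell makes them only quasi-equal."""
        sharp, mask = sphere40
        roi = _roi_from(sharp, mask)
        lb = run_lbpvc(sharp, roi, psf=PsfModel(8.0))
        gb = run_gbpvc(sharp, roi, psf=PsfModel(8.0))
        assert lb.c_mean_corrected == pytest.approx(gb.c_mean_corrected, rel=1e-12)

        grid, mask = blurred_sphere40
        roi = _roi_from(grid, mask)
        lb = run_lbpvc(grid, roi, psf=PsfModel(8.0))
        gb = run_gbpvc(grid, roi, psf=PsfModel(8.0))
        assert lb.c_mean_corrected == pytest.approx(gb.c_mean_corrected, rel=5e-3)

    def test_underestimated_fwhm_collects_less_spillout(self, blurred_sphere40):
        """Assuming 4 mm resolution on 8 mm data shrinks the spill-out shell
        and the correction (the systematic-underestimate mechanism)."""
        grid, mask = blurred_sphere40
        roi = _roi_from(grid, mask)
        res4 = run_lbpvc(grid, roi, psf=PsfModel(4.0))
        res8 = run_lbpvc(grid, roi, psf=PsfModel(8.0))
        assert res4.a_sp < res8.a_sp
        assert res4.c_mean_corrected < res8.c_mean_corrected

    def test_step_background_lbpvc_beats_gbpvc(self):
        """Two-level background with the lesion sitting mostly on the low
        side, its edge near the step: the local estimator tracks each side,
        while the global mean is pulled up by the hot part of the shell and
        overcorrects the majority of spill-out voxels.  (A lesion centred
        exactly on the step is a degenerate case where the shell sum
        cancels the error of the global estimate by symmetry.)"""
        n = 41
        x = 4.0 * np.arange(n)
        c = 4.0 * (n - 1) / 2.0
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        cx = c - 12.0  # lesion centre 12 mm left of the step
        r = np.sqrt((X - cx) ** 2 + (Y - c) ** 2 + (Z - c) ** 2)
        mask = r <= 14.0
        background = np.where(X < c + 14.0, 0.5, 2.0)
        sharp = np.where(mask, 8.0, background)
        from hotpvc import gaussian_smooth

        grid = VoxelGrid(sharp, (4.0,) * 3)
        blurred = gaussian_smooth(grid, PsfModel(8.0))
        true_mean = sharp[mask].mean()
        roi = _roi_from(blurred, mask)
        lb = run_lbpvc(blurred, roi, psf=PsfModel(8.0))
        gb = run_gbpvc(blurred, roi, psf=PsfModel(8.0))
        assert abs(lb.c_mean_corrected - true_mean) < abs(gb.c_mean_corrected - true_mean)

    def test_neighbour_exclusion_changes_background(self):
        grid, mask = make_sphere_grid(n=41, radius_mm=12.0, centre_offset_mm=(-20, 0, 0))
        other = np.zeros(grid.shape, bool)
        # hot neighbour inside the background shell (shell reaches ~voxel 23)
        other[21:24, 18:22, 18:22] = True
        vals = grid.values.copy()
        vals[other] = 50.0
        from hotpvc import gaussian_smooth

        blurred = gaussian_smooth(grid.with_values(vals), PsfModel(8.0))
        roi = _roi_from(blurred, mask)
        with_excl = run_lbpvc(blurred, roi, [other], psf=PsfModel(8.0))
        without = run_lbpvc(blurred, roi, psf=PsfModel(8.0))
        assert with_excl.global_background < without.global_background

    @given(scale=st.floats(0.1, 10.0), offset=st.floats(-2.0, 2.0))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_linearity_and_background_shift_equivariance(self, scale, offset):
        """Scaling the image by k scales a_roi, a_sp and the corrected mean
        by k; adding a constant b leaves (corrected - b) unchanged."""
        grid, mask = make_sphere_grid(n=29, radius_mm=12.0, amplitude=6.0, background=1.0)
        from hotpvc import gaussian_smooth

        blurred = gaussian_smooth(grid, PsfModel(8.0))
        psf = PsfModel(8.0)
        base = run_lbpvc(blurred, _roi_from(blurred, mask), psf=psf)

        scaled_grid = blurred.with_values(blurred.values * scale)
        scaled = run_lbpvc(scaled_grid, _roi_from(scaled_grid, mask), psf=psf)
        assert scaled.a_sp == pytest.approx(scale * base.a_sp, rel=1e-9, abs=1e-12)
        assert scaled.c_mean_corrected == pytest.approx(
            scale * base.c_mean_corrected, rel=1e-9
        )

        shifted_grid = blurred.with_values(blurred.values + offset)
        shifted = run_lbpvc(shifted_grid, _roi_from(shifted_grid, mask), psf=psf)
        assert shifted.c_mean_corrected - offset == pytest.approx(
            base.c_mean_corrected, rel=1e-9, abs=1e-9
        )

    def test_result_invariant_corrected_mean_identity(self, blurred_sphere40):
        grid, mask = blurred_sphere40
        res = run_lbpvc(grid, _roi_from(grid, mask), psf=PsfModel(8.0))
        assert res.c_mean_corrected == pytest.approx(
            (res.a_roi + res.a_sp) / res.v_roi_ml, rel=1e-12
        )
        assert res.n_fallback_voxels <= res.n_spillout_voxels
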