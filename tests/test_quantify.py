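"""Tests of the quantification chain: IVSD, TKE, segmentation, profiles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import stenoflow as sf
from conftest import make_uniform_flow
from stenoflow.quantify import regrid, rmse_compare


def _signals_for(flow, venc, **cfg_kw):
    cfg = sf.AcquisitionConfig(venc=venc, te=3e-3, tr=8e-3, displacement=False, **cfg_kw)
    return sf.acquire(flow, None, cfg)


class TestIvsdInversion:
    def test_closed_form_example(self):
        # |S_d|/|S_0| = exp(-1/2) at VENC 0.35 inverts to sigma = venc/pi
        flow = make_uniform_flow((0.0, 0.0, 0.0), (0.35 / np.pi,) * 3)
        ivsd, info = sf.ivsd_from_magnitude(_signals_for(flow, venc=0.35))
        m = flow.lumen_mask
        np.testing.assert_allclose(ivsd[:, m], 0.35 / np.pi, rtol=1e-12)
        assert (0.35 / np.pi) == pytest.approx(0.1114, abs=1e-4)

    def test_equal_magnitudes_give_zero_sigma(self):
        flow = make_uniform_flow((0.1, 0.0, 0.0))
        ivsd, info = sf.ivsd_from_magnitude(_signals_for(flow, venc=0.35))
        m = flow.lumen_mask
        np.testing.assert_allclose(ivsd[:, m], 0.0, atol=1e-12)

    def test_zero_reference_voxels_flagged_missing(self, flow_re2000):
        cfg = sf.AcquisitionConfig(venc=0.35, te=3e-3, tr=8e-3, displacement=False)
        sig = sf.acquire(flow_re2000, None, cfg)
        ivsd, info = sf.ivsd_from_magnitude(sig)
        assert info["n_missing"] > 0
        assert np.all(np.isnan(ivsd[:, ~flow_re2000.lumen_mask]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(sigma_kv=st.floats(0.01, 2.0), venc=st.floats(0.1, 2.0))
    def test_round_trip_is_exact_inverse(self, sigma_kv, venc):
        """Forward signal then inversion recovers sigma to < 1e-10 m/s."""
        sigma = sigma_kv * venc / np.pi
        flow = make_uniform_flow((0.0, 0.0, 0.0), (sigma,) * 3, shape=(6, 8, 8))
        ivsd, _ = sf.ivsd_from_magnitude(_signals_for(flow, venc=venc))
        m = flow.lumen_mask
        assert np.max(np.abs(ivsd[:, m] - sigma)) < 1e-10

    def test_still_fluid_tke_decreases_with_noise(self):
        """In zero-flow regions with signal, the clamped estimator's median
        TKE shrinks toward zero as the noise level does."""
        medians = []
        for ns in (0.1, 0.03, 0.01):
            flow = make_uniform_flow((0.0, 0.0, 0.0), shape=(10, 12, 12))
            sig = _signals_for(flow, venc=0.35, noise_sigma=ns, seed=5)
            ivsd, _ = sf.ivsd_from_magnitude(sig)
            tmap = sf.tke_from_ivsd(np.nan_to_num(ivsd), 997.0, flow.grid)
            medians.append(np.median(tmap.tke[flow.lumen_mask]))
        assert medians[0] > medians[1] > medians[2]
        # roughly linear in the noise level: 10x less noise, ~10x less TKE
        assert medians[2] < 0.15 * medians[0]


class TestTke:
    def test_arithmetic(self, grid):
        ivsd = np.full((3, 2, 2, 2), 0.1)
        g = sf.GridSpec((2, 2, 2), 1.5e-3, (0, 0, 0))
        tmap = sf.tke_from_ivsd(ivsd, 997.0, g)
        np.testing.assert_allclose(tmap.tke, 14.955, rtol=1e-12)

    def test_zero_ivsd_gives_zero(self):
        g = sf.GridSpec((2, 2, 2), 1.5e-3, (0, 0, 0))
        tmap = sf.tke_from_ivsd(np.zeros((3, 2, 2, 2)), 997.0, g)
        assert np.all(tmap.tke == 0.0)

    def test_isotropic_identity(self):
        g = sf.GridSpec((2, 2, 2), 1.5e-3, (0, 0, 0))
        sigma = 0.07
        tmap = sf.tke_from_ivsd(np.full((3, 2, 2, 2), sigma), 997.0, g)
        np.testing.assert_allclose(tmap.tke, 1.5 * 997.0 * sigma**2, rtol=1e-12)

    def test_negative_density_rejected(self):
        g = sf.GridSpec((2, 2, 2), 1.5e-3, (0, 0, 0))
        with pytest.raises(ValueError):
            sf.tke_from_ivsd(np.zeros((3, 2, 2, 2)), -1.0, g)


class TestTotalTke:
    def test_uniform_field_sums_exactly(self, geometry, grid, segmentation):
        tke = np.zeros(grid.shape)
        X = geometry.x_to_diameters(grid.axis_centers(0))
        sel = (X >= 0) & (X <= 6)
        tke[sel] = 2.5  # J/m^3 everywhere in range
        ivsd = np.zeros((3, *grid.shape))
        tmap = sf.TurbulenceMap(ivsd=ivsd, tke=tke, density=997.0, grid=grid)
        n = int(np.count_nonzero(segmentation.mask[sel]))
        expected = 2.5 * n * grid.voxel_volume
        assert sf.total_tke(tmap, segmentation, geometry) == pytest.approx(expected)

    def test_out_of_range_voxels_excluded(self, geometry, grid, segmentation):
        tke = np.ones(grid.shape)
        X = geometry.x_to_diameters(grid.axis_centers(0))
        tke[(X >= 0) & (X <= 6)] = 0.0  # energy only outside the window
        tmap = sf.TurbulenceMap(np.zeros((3, *grid.shape)), tke, 997.0, grid)
        assert sf.total_tke(tmap, segmentation, geometry) == 0.0

    def test_end_to_end_recovery_from_generator_target(
        self, geometry, grid, segmentation
    ):
        cond = sf.flow_condition(20e-6, geometry)
        flow = sf.turbulence_field(
            geometry, cond, grid, sf.TurbulenceParameters(total_tke=9.5e-5)
        )
        cfg = sf.AcquisitionConfig.from_protocol(
            "stack_of_spirals", "TRA", 35, displacement=False
        )
        ivsd, info = sf.ivsd_from_magnitude(sf.acquire(flow, None, cfg))
        tmap = sf.tke_from_ivsd(ivsd, 997.0, grid, info["n_clamped"])
        assert sf.total_tke(tmap, segmentation, geometry) == pytest.approx(9.5e-5, rel=0.05)


class TestSegmentation:
    def test_straight_section_area(self, geometry, grid, segmentation):
        # upstream plane: pi R^2 within about one voxel ring of perimeter
        area = np.pi * geometry.radius**2 / grid.voxel_size**2
        ring = 2 * np.pi * geometry.radius / grid.voxel_size
        count = segmentation.mask[1].sum()
        assert abs(count - area) <= ring

    def test_throat_area_is_quarter(self, geometry, grid, segmentation):
        X = geometry.x_to_diameters(grid.axis_centers(0))
        i0 = int(np.argmin(np.abs(X)))
        ratio = segmentation.mask[i0].sum() / segmentation.mask[1].sum()
        # 75% area reduction; generous tolerance for voxelization
        assert ratio == pytest.approx(0.25, abs=0.07)

    def test_transverse_connectivity(self, segmentation):
        from scipy.ndimage import label

        for plane in segmentation.mask[::7]:
            _, n = label(plane)
            assert n == 1


class TestMaxVelocity:
    def test_constant_speed_preserved(self):
        flow = make_uniform_flow((0.4, 0.0, 0.0))
        seg = sf.Segmentation(mask=flow.lumen_mask, grid=flow.grid)
        # erode: keep only the central axis where smoothing sees mostly lumen
        rec = sf.ReconResult(
            magnitude=np.ones(flow.grid.shape),
            velocity=np.full((3, *flow.grid.shape), 0.0),
            venc=1.0,
            grid=flow.grid,
        )
        rec.velocity[0] = 0.4  # constant over the whole grid
        assert sf.max_velocity(rec, seg) == pytest.approx(0.4, rel=1e-6)

    def test_single_voxel_spike_attenuated(self):
        shape = (11, 11, 11)
        g = sf.GridSpec(shape, 1.5e-3, (0, 0, 0))
        vel = np.zeros((3, *shape))
        vel[0, 5, 5, 5] = 1.0
        rec = sf.ReconResult(np.ones(shape), vel, 1.0, g)
        seg = sf.Segmentation(np.ones(shape, dtype=bool), g)
        assert sf.max_velocity(rec, seg) < 0.5

    def test_empty_mask_rejected(self):
        shape = (4, 4, 4)
        g = sf.GridSpec(shape, 1.5e-3, (0, 0, 0))
        rec = sf.ReconResult(np.ones(shape), np.zeros((3, *shape)), 1.0, g)
        with pytest.raises(ValueError):
            sf.max_velocity(rec, sf.Segmentation(np.zeros(shape, dtype=bool), g))

    def test_matches_ground_truth_smoothed_maximum(self, geometry, flow_increased,
                                                   segmentation):
        # VENC 300 keeps the jet peak (~1.7 m/s) well inside the unaliased range
        cfg = sf.AcquisitionConfig.from_protocol(
            "stack_of_spirals", "COR", 300, displacement=False
        )
        rec = sf.velocity_from_phase(sf.acquire(flow_increased, None, cfg))
        measured = sf.max_velocity(rec, segmentation)
        from scipy.ndimage import gaussian_filter

        truth = np.sqrt(np.sum(flow_increased.mean_velocity**2, axis=0))
        smoothed = gaussian_filter(truth, sigma=5.0 / 4.0, mode="nearest")
        oracle = smoothed[segmentation.mask].max()
        assert measured == pytest.approx(oracle, rel=0.05)


class TestFlowRateProfile:
    def test_uniform_plug_integrates_to_u_times_area(self):
        flow = make_uniform_flow((0.3, 0.0, 0.0))
        seg = sf.Segmentation(flow.lumen_mask, flow.grid)
        rec = sf.ReconResult(np.ones(flow.grid.shape), flow.mean_velocity, 1.0, flow.grid)
        prof = sf.flow_rate_profile(rec, seg, [0.0], flow.geometry)
        n_pix = flow.lumen_mask[flow.grid.shape[0] // 2].sum()
        assert prof.flow_rate[0] == pytest.approx(0.3 * n_pix * flow.grid.voxel_size**2)

    def test_sign_preserved_for_reversed_flow(self):
        flow = make_uniform_flow((-0.3, 0.0, 0.0))
        seg = sf.Segmentation(flow.lumen_mask, flow.grid)
        rec = sf.ReconResult(np.ones(flow.grid.shape), flow.mean_velocity, 1.0, flow.grid)
        prof = sf.flow_rate_profile(rec, seg, [0.0], flow.geometry)
        assert prof.flow_rate[0] < 0

    def test_poiseuille_plane_recovers_q(self, geometry, flow_increased, segmentation):
        rec = sf.ReconResult(
            np.ones(flow_increased.grid.shape),
            flow_increased.mean_velocity,
            3.0,
            flow_increased.grid,
        )
        prof = sf.flow_rate_profile(rec, segmentation, [-1.5, -1.0, 7.0], geometry)
        np.testing.assert_allclose(prof.flow_rate, 56e-6, rtol=0.01)

    def test_plane_outside_grid_rejected(self, geometry, flow_increased, segmentation):
        rec = sf.ReconResult(
            np.ones(flow_increased.grid.shape),
            flow_increased.mean_velocity,
            3.0,
            flow_increased.grid,
        )
        with pytest.raises(ValueError):
            sf.flow_rate_profile(rec, segmentation, [25.0], geometry)


class TestCenterlineProfile:
    def test_constant_field(self, geometry, grid):
        vol = np.full(grid.shape, 3.25)
        prof = sf.centerline_profile(vol, grid, geometry, np.linspace(-1, 6, 15))
        np.testing.assert_allclose(prof.values, 3.25)

    def test_linear_field_is_exact(self, geometry, grid):
        x = grid.axis_centers(0)[:, None, None]
        vol = np.broadcast_to(2.0 * x + 0.1, grid.shape).copy()
        xs = np.linspace(-1, 6, 12)
        prof = sf.centerline_profile(vol, grid, geometry, xs)
        np.testing.assert_allclose(
            prof.values, 2.0 * geometry.diameters_to_x(xs) + 0.1, rtol=1e-10
        )

    def test_extrapolation_rejected(self, geometry, grid):
        with pytest.raises(ValueError):
            sf.centerline_profile(np.zeros(grid.shape), grid, geometry, [50.0])

    def test_jet_peak_location_matches_fine_grid_oracle(self, geometry):
        cond = sf.flow_condition(56e-6, geometry)
        coarse = sf.mean_velocity_field(geometry, cond)
        fine_grid = sf.default_grid(geometry, voxel_size=0.75e-3)
        fine = sf.mean_velocity_field(geometry, cond, fine_grid)
        xs = np.arange(-1.0, 6.0, 0.1)
        pc = sf.centerline_profile(coarse.mean_velocity[0], coarse.grid, geometry, xs)
        pf = sf.centerline_profile(fine.mean_velocity[0], fine.grid, geometry, xs)
        assert abs(xs[np.argmax(pc.values)] - xs[np.argmax(pf.values)]) <= 0.5


class TestRegridAndRmse:
    def test_identity_on_same_grid(self, grid):
        rng = np.random.default_rng(0)
        vol = rng.standard_normal(grid.shape)
        np.testing.assert_allclose(regrid(vol, grid, grid), vol, atol=1e-12)

    def test_constant_field_any_grid(self, grid):
        vol = np.full(grid.shape, 1.7)
        target = sf.GridSpec((40, 12, 12), 2.1e-3, (-0.02, -0.012, -0.012))
        out = regrid(vol, grid, target)
        np.testing.assert_allclose(out[np.isfinite(out)], 1.7, atol=1e-12)

    def test_out_of_fov_flagged_nan(self, grid):
        target = sf.GridSpec(
            grid.shape, grid.voxel_size,
            (grid.origin[0] - 0.05, grid.origin[1], grid.origin[2]),
        )
        out = regrid(np.ones(grid.shape), grid, target)
        assert np.isnan(out[0]).all()

    def test_disjoint_fov_rejected(self, grid):
        target = sf.GridSpec((4, 4, 4), 1.5e-3, (10.0, 10.0, 10.0))
        with pytest.raises(ValueError):
            regrid(np.ones(grid.shape), grid, target)

    def test_second_order_convergence(self):
        def field(g):
            x, y, z = g.center_mesh()
            return np.sin(60 * x) * np.cos(55 * y) + (50 * z) ** 2

        target = sf.GridSpec((16, 16, 16), 2.0e-3, (2e-4, 3e-4, 1e-4))
        errs = []
        for h in (1.0e-3, 0.5e-3):
            n = int(0.04 / h)
            src = sf.GridSpec((n, n, n), h, (0.0, 0.0, 0.0))
            out = regrid(field(src), src, target)
            truth = field(target)
            sel = np.isfinite(out)
            errs.append(np.max(np.abs(out[sel] - truth[sel])))
        # halving the source spacing should cut the error ~4x; demand 2x
        assert errs[1] <= 0.5 * errs[0]

    def test_rmse_trivial_cases(self, grid, segmentation):
        rng = np.random.default_rng(1)
        a = rng.standard_normal(grid.shape)
        assert rmse_compare(a, a, segmentation) == 0.0
        assert rmse_compare(a + 0.37, a, segmentation) == pytest.approx(0.37)

    def test_rmse_matches_brute_force(self, grid, segmentation):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(grid.shape)
        b = rng.standard_normal(grid.shape)
        m = segmentation.mask
        brute = np.sqrt(np.mean((a[m] - b[m]) ** 2))
        assert rmse_compare(a, b, segmentation) == pytest.approx(brute, rel=1e-12)
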