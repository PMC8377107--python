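"""Acquisition model: PSF, conservation, attenuation, adjointness, noise."""

import numpy as np
import pytest

from spectquant.phantoms import VoxelGrid, make_point_source
from spectquant.presets import DEFAULT_ORBIT_RADIUS_CM, get_preset
from spectquant.projector import (
    ModelFlags,
    Projector,
    Protocol,
    build_psf_kernel,
    forward_project,
    psf_fwhm_at_distance,
    simulate_acquisition,
)


class TestSystemResolution:
    def test_zero_collimator_terms_give_intrinsic(self, camera_me):
        cam = camera_me.with_(collimator_slope=0.0, collimator_intercept=0.0)
        for d in (0.0, 10.0, 30.0):
            assert psf_fwhm_at_distance(cam, d) == pytest.approx(cam.fwhm_intrinsic)

    def test_fwhm_strictly_increasing_with_distance(self, any_camera):
        d = np.linspace(0, 40, 50)
        fwhm = psf_fwhm_at_distance(any_camera, d)
        assert (np.diff(fwhm) > 0).all()

    def test_high_energy_preset_resolution_anchor(self):
        """The HE system resolution at the default orbit is ~1.3 cm planar."""
        fwhm = psf_fwhm_at_distance(get_preset("I131_HE"), DEFAULT_ORBIT_RADIUS_CM)
        assert fwhm == pytest.approx(13.0, abs=0.5)

    def test_negative_distance_rejected(self, camera_me):
        with pytest.raises(ValueError):
            psf_fwhm_at_distance(camera_me, -1.0)


class TestPsfKernel:
    def test_no_penetration_is_single_gaussian(self, camera_me):
        cam = camera_me.with_(penetration_fraction=0.0)
        k = build_psf_kernel(cam, 20.0, 4.8)
        assert k.sum() == pytest.approx(1.0, abs=1e-6)
        assert k.max() == k[k.shape[0] // 2, k.shape[1] // 2]

    @pytest.mark.parametrize("name", ["I123_LEHR", "I123_ME", "I131_HE"])
    @pytest.mark.parametrize("distance", [5.0, 15.0, 30.0])
    def test_unit_mass(self, name, distance):
        k = build_psf_kernel(get_preset(name), distance, 4.8)
        assert k.sum() == pytest.approx(1.0, abs=1e-6)

    def test_penetration_tail_mass_ordering(self):
        """High penetration (LEHR) puts more kernel mass outside 2 FWHM than ME."""
        def tail_mass(name):
            cam = get_preset(name)
            k = build_psf_kernel(cam, 25.0, 4.8)
            n = k.shape[0]
            u = np.arange(n) - n // 2
            r = np.hypot(u[:, None], u[None, :]) * 4.8
            return k[r > 2.0 * psf_fwhm_at_distance(cam, 25.0)].sum()

        assert tail_mass("I123_LEHR") > tail_mass("I123_ME")

    def test_clipping_logs_warning(self, camera_me, caplog):
        with caplog.at_level("WARNING"):
            k = build_psf_kernel(camera_me, 35.0, 1.0, max_size=15)
        assert k.shape == (15, 15)
        assert k.sum() == pytest.approx(1.0, abs=1e-6)
        assert any("clip" in r.message for r in caplog.records)


class TestForwardModel:
    def test_zero_activity_projects_to_zero(self, tiny_grid, tiny_protocol,
                                            camera_me, all_flags):
        maps = make_point_source(tiny_grid, 1.0)
        maps.activity[:] = 0.0
        assert not forward_project(maps, camera_me, tiny_protocol, all_flags).counts.any()

    def test_count_conservation_point_in_air(self, reduced_grid, reduced_protocol,
                                             any_camera, all_flags):
        """Total counts for a source in air equal sensitivity x A x t (<=0.5%)."""
        maps = make_point_source(reduced_grid, 1.0, center=(30.0, -20.0, 10.0))
        pset = forward_project(maps, any_camera, reduced_protocol, all_flags)
        expected = any_camera.sensitivity * 1.0 * reduced_protocol.total_time
        assert pset.total_counts == pytest.approx(expected, rel=0.005)

    def test_beer_lambert_through_slab(self, reduced_grid, reduced_protocol, camera_me):
        """Counts behind a water slab follow exp(-mu T) to 1e-3."""
        act = reduced_grid.zeros()
        act[20, 32, 32] = 1.0
        mu_air = reduced_grid.zeros()
        mu_slab = reduced_grid.zeros()
        mu_w = 0.148
        mu_slab[30:40] = mu_w       # 10 voxels = 9.6 cm of water toward the detector
        flags = ModelFlags(attenuation=True, cdr=False, scatter=False)
        air = Projector(reduced_grid, camera_me, reduced_protocol, flags, mu=mu_air)
        slab = Projector(reduced_grid, camera_me, reduced_protocol, flags, mu=mu_slab)
        ratio = slab.forward(act, views=[0]).sum() / air.forward(act, views=[0]).sum()
        assert ratio == pytest.approx(np.exp(-mu_w * 9.6), rel=1e-3)

    def test_attenuation_never_increases_counts(self, tiny_grid, tiny_protocol,
                                                camera_me, rng):
        act = rng.uniform(0, 1, tiny_grid.shape)
        flags = ModelFlags(attenuation=True, cdr=True, scatter=False)
        thin = Projector(tiny_grid, camera_me, tiny_protocol, flags,
                         mu=np.full(tiny_grid.shape, 0.01))
        thick = Projector(tiny_grid, camera_me, tiny_protocol, flags,
                          mu=np.full(tiny_grid.shape, 0.05))
        assert (thick.forward(act) <= thin.forward(act) + 1e-12).all()

    def test_view_sum_invariance_for_centred_source(self, reduced_grid,
                                                    reduced_protocol, camera_me,
                                                    all_flags):
        maps = make_point_source(reduced_grid, 1.0)
        pset = forward_project(maps, camera_me, reduced_protocol, all_flags)
        per_view = pset.counts.sum(axis=(1, 2))
        assert per_view.std() / per_view.mean() < 0.01

    def test_linearity(self, tiny_grid, tiny_protocol, camera_me, all_flags, rng):
        mu = rng.uniform(0, 0.05, tiny_grid.shape)
        proj = Projector(tiny_grid, camera_me, tiny_protocol, all_flags, mu=mu)
        x = rng.uniform(0, 1, tiny_grid.shape)
        y = rng.uniform(0, 1, tiny_grid.shape)
        combo = proj.forward(2.0 * x + 3.0 * y)
        parts = 2.0 * proj.forward(x) + 3.0 * proj.forward(y)
        np.testing.assert_allclose(combo, parts, rtol=1e-12, atol=1e-9)

    def test_adjointness_inner_product(self, tiny_grid, tiny_protocol, camera_me,
                                       all_flags, rng):
        """<FP x, y> = <x, BP y> within 1e-4 relative on a 32^3 grid."""
        mu = rng.uniform(0, 0.1, tiny_grid.shape)
        proj = Projector(tiny_grid, camera_me, tiny_protocol, all_flags, mu=mu)
        x = rng.uniform(0, 1, tiny_grid.shape)
        y = rng.uniform(0, 1, (tiny_protocol.n_views,) + tiny_protocol.detector_bins)
        lhs = np.vdot(proj.forward(x), y)
        rhs = np.vdot(x, proj.adjoint(y))
        assert abs(lhs - rhs) / abs(lhs) < 1e-4

    def test_grid_detector_mismatch_rejected(self, tiny_grid, camera_me, all_flags):
        proto = Protocol(n_views=12, detector_bins=(64, 64), bin_size=19.2)
        with pytest.raises(ValueError, match="detector"):
            Projector(tiny_grid, camera_me, proto, all_flags,
                      mu=tiny_grid.zeros())


class TestNoiseModel:
    def test_zero_mean_bins_stay_zero(self, tiny_grid, tiny_protocol, camera_me):
        maps = make_point_source(tiny_grid, 1.0)
        pset = simulate_acquisition(maps, camera_me, tiny_protocol, seed=7)
        noise_free = forward_project(maps, camera_me, tiny_protocol)
        assert not pset.counts[noise_free.counts == 0].any()

    def test_same_seed_bit_identical(self, tiny_grid, tiny_protocol, camera_me):
        maps = make_point_source(tiny_grid, 5.0)
        a = simulate_acquisition(maps, camera_me, tiny_protocol, seed=11)
        b = simulate_acquisition(maps, camera_me, tiny_protocol, seed=11)
        assert np.array_equal(a.counts, b.counts)

    def test_poisson_totals_within_counting_error(self, tiny_grid, tiny_protocol,
                                                  camera_me):
        maps = make_point_source(tiny_grid, 50.0)   # > 1e6 expected counts
        expected = forward_project(maps, camera_me, tiny_protocol).total_counts
        assert expected > 1e6
        a = simulate_acquisition(maps, camera_me, tiny_protocol, seed=1)
        b = simulate_acquisition(maps, camera_me, tiny_protocol, seed=2)
        assert abs(a.total_counts - expected) < 3 * np.sqrt(expected)
        assert not np.array_equal(a.counts, b.counts)
        assert abs(a.total_counts - b.total_counts) < 6 * np.sqrt(expected)
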