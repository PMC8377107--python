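"""Quantification chain: VOI statistics, CF, RC fitting and error arithmetic."""

import statistics

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.ndimage import gaussian_filter
from scipy.special import erf

from spectquant.phantoms import VoxelGrid, _sphere_occupancy
from spectquant.presets import get_preset
from spectquant.projector import ModelFlags, Protocol
from spectquant.quantify import (
    VOI,
    CalibrationFactor,
    RecoveryCurve,
    compute_cf,
    compute_rc,
    count_stats,
    fit_recovery_curve,
    quantify_activity,
)
from spectquant.recon import ReconSettings, ReconVolume


def _volume_from(values, voxel=9.6):
    grid = VoxelGrid(values.shape, voxel)
    return ReconVolume(values=values, grid=grid,
                       settings=ReconSettings(n_subsets=1, n_updates=1),
                       camera=get_preset("I123_ME"),
                       protocol=Protocol(n_views=1, detector_bins=values.shape[1:],
                                         bin_size=voxel))


def _mask_voi(mask):
    return VOI(shape="mask", mask=mask, diameter=1.0)


class TestCountStats:
    def test_hand_computed_example(self):
        vals = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), dtype=bool)
        vals[0, 0, :3] = [1.0, 2.0, 3.0]
        mask[0, 0, :3] = True
        st_ = count_stats(_volume_from(vals), _mask_voi(mask))
        assert st_.mean == pytest.approx(2.0)
        assert st_.sd == pytest.approx(1.0)          # sample (n-1) convention
        assert st_.sd_relative == pytest.approx(50.0)
        assert st_.total == pytest.approx(6.0)
        assert st_.n_voxels == 3

    def test_uniform_voi_has_zero_relative_sd(self):
        vals = np.full((8, 8, 8), 3.7)
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[2:5, 2:5, 2:5] = True
        assert count_stats(_volume_from(vals), _mask_voi(mask)).sd_relative \
            == pytest.approx(0.0, abs=1e-9)

    def test_empty_voi_rejected(self):
        vals = np.zeros((8, 8, 8))
        with pytest.raises(ValueError, match="empty"):
            count_stats(_volume_from(vals), _mask_voi(np.zeros((8, 8, 8), bool)))

    def test_zero_mean_flags_undefined_noise(self, caplog):
        vals = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        mask[:2, 0, 0] = True
        with caplog.at_level("WARNING"):
            st_ = count_stats(_volume_from(vals), _mask_voi(mask))
        assert np.isnan(st_.sd_relative)

    @given(st.lists(st.floats(0.1, 1e4), min_size=3, max_size=20))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_matches_independent_statistics(self, values):
        vals = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        flat = np.array(values)
        mask.ravel()[: flat.size] = True
        vals.ravel()[: flat.size] = flat
        st_ = count_stats(_volume_from(vals), _mask_voi(mask))
        assert st_.mean == pytest.approx(statistics.fmean(flat))
        if len(set(flat)) > 1:
            assert st_.sd == pytest.approx(statistics.stdev(flat))
            assert st_.sd_relative == pytest.approx(
                100.0 * statistics.stdev(flat) / statistics.fmean(flat))


class TestCalibrationFactor:
    def test_unit_example(self):
        vals = np.zeros((8, 8, 8))
        mask = np.zeros((8, 8, 8), bool)
        vals[4, 4, 4] = 1000.0
        mask[4, 4, 4] = True
        cf = compute_cf(_volume_from(vals), _mask_voi(mask), activity=1.0,
                        time=1000.0)
        assert cf.value == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        vals = np.ones((8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        with pytest.raises(ValueError):
            compute_cf(_volume_from(vals), _mask_voi(mask), activity=0.0, time=1.0)

    def test_zero_counts_flagged_suspect(self, caplog):
        vals = np.zeros((8, 8, 8))
        mask = np.ones((8, 8, 8), bool)
        with caplog.at_level("WARNING"):
            cf = compute_cf(_volume_from(vals), _mask_voi(mask), 1.0, 1.0)
        assert cf.suspect and cf.value == 0.0

    @given(st.floats(1e-3, 1e3), st.floats(1e-3, 1e3))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_rc_is_plain_ratio(self, rec, true):
        assert compute_rc(rec, true) == pytest.approx(rec / true)

    def test_rc_rejects_nonpositive_truth(self):
        with pytest.raises(ValueError):
            compute_rc(1.0, 0.0)


class TestRecoveryCurveFit:
    def test_exact_data_recovered(self):
        d = np.array([1.0, 2.0, 3.0, 5.0, 8.0, 12.0])
        rc = 1.0 - 1.0 * np.exp(-0.5 * d)
        fit = fit_recovery_curve(d, rc)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.b == pytest.approx(1.0, abs=1e-6)
        assert fit.c == pytest.approx(0.5, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_matches_grid_search_oracle(self, rng):
        d = np.array([2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0])
        rc = 0.95 - 0.8 * np.exp(-0.45 * d) + rng.normal(0, 0.01, d.size)

        def sse(a, b, c):
            return ((rc - (a - b * np.exp(-c * d))) ** 2).sum()

        fit = fit_recovery_curve(d, rc)
        best = min(
            sse(a, b, c)
            for a in np.linspace(0.85, 1.05, 41)
            for b in np.linspace(0.6, 1.0, 41)
            for c in np.linspace(0.3, 0.6, 31)
        )
        assert sse(fit.a, fit.b, fit.c) <= best + 1e-6

    def test_fitted_curve_monotone_on_range(self):
        d = np.array([2.5, 3.0, 4.0, 5.0, 6.0, 7.0, 8.0, 10.0])
        rc = np.array([0.66, 0.69, 0.78, 0.82, 0.85, 0.87, 0.89, 0.91])
        fit = fit_recovery_curve(d, rc)
        grid = np.linspace(d.min(), d.max(), 100)
        pred = fit.a - fit.b * np.exp(-fit.c * grid)
        assert (np.diff(pred) >= 0).all()
        assert 0 < pred.min() and pred.max() <= 1.1

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_recovery_curve([1, 2, 3], [0.5, 0.6, 0.7])

    def test_extrapolation_warns(self, caplog):
        curve = RecoveryCurve(a=0.9, b=0.6, c=0.4, r_squared=1.0,
                              diameters=(2.5, 10.0), rcs=(0.6, 0.9))
        with caplog.at_level("WARNING"):
            curve.predict(14.0)
        assert any("outside fitted range" in r.message for r in caplog.records)


class TestRcBlurOracle:
    def test_blurred_sphere_matches_closed_form(self):
        """In-sphere mean of a Gaussian-blurred ball vs the radial closed form."""
        grid = VoxelGrid((96, 96, 96), 2.0)
        R, sigma = 30.0, 6.0                     # mm
        occ = _sphere_occupancy(grid, (0.5, 0.5, 0.5), R, 4)
        blurred = gaussian_filter(occ, sigma / grid.voxel_size, mode="constant")
        measured = float((blurred * occ).sum() / occ.sum())

        def profile(r):
            r = np.maximum(r, 1e-9)
            a = 0.5 * (erf((r + R) / (sigma * np.sqrt(2)))
                       - erf((r - R) / (sigma * np.sqrt(2))))
            b = sigma / (r * np.sqrt(2 * np.pi)) * (
                np.exp(-((r - R) ** 2) / (2 * sigma**2))
                - np.exp(-((r + R) ** 2) / (2 * sigma**2)))
            return a - b

        r = np.linspace(1e-6, R, 2000)
        oracle = float(np.trapezoid(profile(r) * r**2, r) * 3.0 / R**3)
        assert compute_rc(measured, 1.0) == pytest.approx(oracle, rel=0.02)


class TestQuantifyActivity:
    def _setup(self, factor=1.0):
        voxel = 9.6
        grid_shape = (8, 8, 8)
        vals = np.zeros(grid_shape)
        mask = np.zeros(grid_shape, bool)
        mask[2:5, 2:5, 2:5] = True
        cf = CalibrationFactor(value=100.0, geometry="point",
                               voi_rule="physical_plus_3cm", camera="I123_ME")
        t, true_conc = 1200.0, 0.7
        voxvol = (voxel / 10) ** 3
        vals[mask] = factor * cf.value * t * voxvol * true_conc
        curve = RecoveryCurve(a=1.0, b=0.0, c=1.0, r_squared=1.0,
                              diameters=(1.0, 20.0), rcs=(1.0, 1.0))
        vol = _volume_from(vals, voxel)
        return vol, _mask_voi(mask), cf, curve, t, true_conc

    def test_perfect_inputs_give_zero_error(self):
        vol, voi, cf, curve, t, conc = self._setup()
        res = quantify_activity(vol, voi, cf, curve, t, conc)
        assert res.error_percent == pytest.approx(0.0, abs=1e-9)

    def test_five_percent_overestimate(self):
        vol, voi, cf, curve, t, conc = self._setup(factor=1.05)
        res = quantify_activity(vol, voi, cf, curve, t, conc)
        assert res.error_percent == pytest.approx(5.0, abs=1e-9)

    @given(st.floats(0.1, 10.0), st.floats(0.1, 10.0))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_error_identity(self, rec, true):
        """Error-percentage arithmetic cross-checked against an independent expression."""
        err = 100.0 * (rec - true) / true
        assert err == pytest.approx(100.0 * (rec / true - 1.0), rel=1e-12)


class TestVoiGeometry:
    def test_rules_realise_expected_diameters(self, reduced_grid):
        voi = VOI(shape="sphere", diameter=6.0, rule="physical_plus_3cm")
        assert voi.realised_diameter(reduced_grid) == pytest.approx(12.0)
        voi = VOI(shape="sphere", diameter=6.0, rule="physical_minus")
        assert voi.realised_diameter(reduced_grid) == pytest.approx(6.0 - 2 * 0.96)
        voi = VOI(shape="sphere", diameter=6.0, rule="detector")
        assert voi.realised_diameter(reduced_grid) == pytest.approx(61.44)

    def test_fractional_weights_sum_to_analytic_volume(self, reduced_grid):
        voi = VOI(shape="sphere", center=(2.4, 2.4, 2.4), diameter=6.0)
        vol_ml = voi.weights_for(reduced_grid).sum() * reduced_grid.voxel_volume_ml
        assert vol_ml == pytest.approx(113.1, rel=0.005)

    def test_unknown_rule_rejected(self):
        with pytest.raises(ValueError):
            VOI(shape="sphere", diameter=1.0, rule="bogus")
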