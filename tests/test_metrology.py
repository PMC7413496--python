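"""Bead detection, Gaussian FWHM fitting and condition summaries."""

import math

import numpy as np
import pytest

from focalmetry import (
    BeadFieldParams,
    ImageStack,
    ImagingCondition,
    PSFSpec,
    generate_bead_stack,
    psf_preset,
)
from focalmetry.errors import EmptyResultError, RangeError, ValidationError
from focalmetry.metrology import (
    FWHM_PER_SIGMA,
    BeadDetection,
    FitMode,
    IntensityProfile,
    ProfileAxis,
    detect_beads,
    expansion_ratio,
    extract_profile,
    fit_gaussian,
    half_max_width,
    measure_bead,
    summarize_condition,
)
from focalmetry.pipeline import measure_bead_stacks, simulate_condition_measurements

PRESET_O100 = PSFSpec(0.41, 2.16)


def _gauss_profile(sigma=1.0, mu=0.0, amp=100.0, offset=0.0, step=0.25, half=4.0,
                   axis=ProfileAxis.AXIAL_Z):
    u = np.arange(-half, half + step / 2, step)
    v = amp * np.exp(-((u - mu) ** 2) / (2 * sigma**2)) + offset
    return IntensityProfile(u, v, axis)


class TestDetection:
    def test_isolated_beads_found_at_true_centers(self):
        params = BeadFieldParams(
            stack_shape=(56, 240, 240), n_beads=5, seed=8, min_separation_um=3.0,
            noise=False, jitter=False, fwhm_cv=0.0,
        )
        stack, truth = generate_bead_stack(params, PRESET_O100)
        dets = detect_beads(stack, 50.0, 3.0, (4.0, 1.5))
        iso = [d for d in dets if d.isolation_ok]
        assert len(iso) == 5
        steps = np.array([stack.axial_step_um, stack.lateral_step_um, stack.lateral_step_um])
        found = sorted(tuple(np.round(d.peak_voxel * steps, 2)) for d in iso)
        for pos, center in zip(found, sorted(map(tuple, np.round(truth.centers_um, 2)))):
            assert np.allclose(pos, center, atol=float(max(steps)))

    def test_crowded_pair_both_excluded(self):
        vox = np.full((20, 60, 60), 1.0)
        vox[10, 30, 15] = 100.0
        vox[10, 30, 35] = 90.0  # 1.0 um apart = 0.5 * min_separation
        stack = ImageStack(vox, 0.05, 0.25)
        dets = detect_beads(stack, 10.0, min_separation_um=2.0, border_margin_um=0.2)
        assert len(dets) == 2
        assert not any(d.isolation_ok for d in dets)

    def test_uniform_stack_yields_nothing(self):
        stack = ImageStack(np.full((10, 20, 20), 3.0), 0.05, 0.25)
        assert detect_beads(stack, 5.0) == []

    def test_equal_intensity_plateau_keeps_first_in_scan_order(self):
        vox = np.zeros((12, 30, 30))
        vox[6, 15, 10] = vox[6, 15, 12] = 50.0
        stack = ImageStack(vox, 0.1, 0.25)
        dets = detect_beads(stack, 1.0, min_separation_um=1.0, border_margin_um=0.1)
        assert len(dets) == 1
        assert dets[0].peak_voxel == (6, 15, 10)


class TestProfiles:
    def test_profile_centred_at_peak_with_axis_step(self):
        params = BeadFieldParams(seed=3, noise=False, jitter=False, fwhm_cv=0.0)
        stack, _ = generate_bead_stack(params, PRESET_O100)
        peak = np.unravel_index(np.argmax(stack.voxels), stack.voxels.shape)
        ax = extract_profile(stack, peak, ProfileAxis.AXIAL_Z)
        lat = extract_profile(stack, peak, ProfileAxis.LATERAL_X)
        assert ax.step_um == pytest.approx(stack.axial_step_um)
        assert lat.step_um == pytest.approx(stack.lateral_step_um)
        assert ax.values[np.searchsorted(ax.positions_um, 0.0)] == ax.values.max()

    def test_window_exceeding_stack_raises(self):
        stack = ImageStack(np.ones((10, 20, 20)), 0.05, 0.25)
        with pytest.raises(RangeError):
            extract_profile(stack, (5, 10, 10), ProfileAxis.AXIAL_Z, window_um=4.0)


class TestGaussianFit:
    def test_exact_gaussian_recovers_analytic_fwhm(self):
        res = fit_gaussian(_gauss_profile(sigma=1.0), FitMode.FREE_CENTER)
        assert res.fwhm_um == pytest.approx(2.0 * math.sqrt(2.0 * math.log(2.0)), abs=1e-6)
        assert res.fwhm_um == pytest.approx(2.3548, abs=1e-3)
        assert res.fit_rmse == pytest.approx(0.0, abs=1e-6)

    def test_offset_recovered_exactly_noise_free(self):
        res = fit_gaussian(_gauss_profile(sigma=0.8, offset=10.0))
        assert res.offset == pytest.approx(10.0, abs=1e-6)

    def test_fixed_center_biases_high_on_off_center_profile(self):
        prof = _gauss_profile(sigma=1.0, mu=0.075)  # 0.3 * step off centre
        free = fit_gaussian(prof, FitMode.FREE_CENTER)
        fixed = fit_gaussian(prof, FitMode.FIXED_CENTER)
        assert fixed.fwhm_um > free.fwhm_um
        assert free.fwhm_um == pytest.approx(FWHM_PER_SIGMA, abs=1e-6)

    def test_fixed_center_never_fits_better_than_free(self, rng):
        for _ in range(10):
            prof = _gauss_profile(
                sigma=rng.uniform(0.6, 1.5), mu=rng.uniform(-0.2, 0.2), offset=5.0
            )
            noisy = IntensityProfile(
                prof.positions_um, prof.values + rng.normal(0, 2, prof.values.shape) + 10,
                prof.axis,
            )
            free = fit_gaussian(noisy, FitMode.FREE_CENTER)
            fixed = fit_gaussian(noisy, FitMode.FIXED_CENTER)
            assert fixed.fit_rmse >= free.fit_rmse - 1e-9

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValidationError):
            fit_gaussian(_gauss_profile(step=2.0, half=5.0))

    @pytest.mark.parametrize("sigma", [0.2, 0.5, 1.0, 1.9])
    @pytest.mark.parametrize("mu", [0.0, 0.37])
    def test_fit_agrees_with_half_max_oracle_on_noiseless_profiles(self, sigma, mu):
        # the model-free crossing oracle and the fit must agree within 0.5%
        prof = _gauss_profile(sigma=sigma, mu=mu * sigma, offset=7.0,
                              step=sigma / 8, half=5 * sigma)
        fitted = fit_gaussian(prof).fwhm_um
        assert fitted == pytest.approx(half_max_width(prof), rel=0.005)

    def test_fit_agrees_with_half_max_oracle_on_rendered_bead(self):
        psf = psf_preset(ImagingCondition(1.33, "overfill", 100))
        params = BeadFieldParams(seed=100, noise=False, jitter=False, fwhm_cv=0.0)
        stack, _ = generate_bead_stack(params, psf)
        peak = np.unravel_index(np.argmax(stack.voxels), stack.voxels.shape)
        prof = extract_profile(stack, peak, ProfileAxis.AXIAL_Z, window_um=5.0)
        assert fit_gaussian(prof).fwhm_um == pytest.approx(half_max_width(prof), rel=0.005)


class TestMeasurement:
    def test_noise_free_bead_measured_to_one_percent(self):
        params = BeadFieldParams(seed=6, noise=False, jitter=False, fwhm_cv=0.0)
        stack, truth = generate_bead_stack(params, PRESET_O100)
        m = measure_bead_stacks([stack])[0]
        assert m.fwhm_xy_um == pytest.approx(truth.true_fwhm[0].fwhm_lateral_um, rel=0.01)
        assert m.fwhm_z_um == pytest.approx(truth.true_fwhm[0].fwhm_axial_um, rel=0.01)

    def test_isotropic_bead_gives_equal_axes(self):
        params = BeadFieldParams(
            stack_shape=(56, 120, 120), seed=1, noise=False, jitter=False, fwhm_cv=0.0
        )
        stack, _ = generate_bead_stack(params, PSFSpec(1.2, 1.2))
        m = measure_bead_stacks([stack])[0]
        assert m.fwhm_xy_um == pytest.approx(m.fwhm_z_um, rel=0.01)

    def test_jittered_bead_fixed_center_still_finite(self):
        params = BeadFieldParams(seed=2, jitter_sd_um=0.1)
        stack, _ = generate_bead_stack(params, PRESET_O100)
        ms = measure_bead_stacks([stack], mode=FitMode.FIXED_CENTER)
        assert ms and np.isfinite(ms[0].fwhm_z_um) and ms[0].fwhm_z_um > 0

    def test_refusing_non_isolated_detection(self):
        stack = ImageStack(np.ones((10, 20, 20)), 0.05, 0.25)
        det = BeadDetection((5, 10, 10), 1.0, False)
        with pytest.raises(ValidationError):
            measure_bead(stack, det)

    def test_recovered_axial_width_grows_with_depth(self):
        # the depth ordering of the shipped presets survives the full
        # simulate -> detect -> fit -> summarize chain
        for fill in ("overfill", "underfill"):
            means = []
            for depth in (100, 200, 300):
                cond = ImagingCondition(1.33, fill, depth)
                ms = simulate_condition_measurements(cond, 5, seed=31)
                means.append(summarize_condition(ms).mean_fwhm_z_um)
            assert means[0] < means[1] < means[2]


class TestSummaries:
    def test_single_measurement_has_no_sem(self):
        params = BeadFieldParams(seed=4, noise=False, jitter=False, fwhm_cv=0.0)
        stack, _ = generate_bead_stack(params, PRESET_O100)
        s = summarize_condition(measure_bead_stacks([stack]))
        assert s.n_beads == 1
        assert s.sem_fwhm_z_um is None

    def test_known_sample_sem(self):
        class M:
            def __init__(self, xy, z):
                self.fwhm_xy_um, self.fwhm_z_um, self.reliable = xy, z, True

        s = summarize_condition([M(1.0, 1.0), M(2.0, 2.0), M(3.0, 3.0)])
        assert s.mean_fwhm_z_um == pytest.approx(2.0)
        assert s.sem_fwhm_z_um == pytest.approx(1.0 / math.sqrt(3.0))
        t = summarize_condition([M(2.0, 2.0)] * 3)
        assert t.sem_fwhm_z_um == pytest.approx(0.0)

    def test_no_reliable_measurements_is_an_error(self):
        with pytest.raises(EmptyResultError):
            summarize_condition([])

    def test_expansion_ratio_identity(self):
        class M:
            def __init__(self, xy, z):
                self.fwhm_xy_um, self.fwhm_z_um, self.reliable = xy, z, True

        s = summarize_condition([M(0.41, 2.16)] * 2)
        assert expansion_ratio(s, s) == pytest.approx((1.0, 1.0))
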