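"""Reconvolution fitting: forward model, parameter recovery, FLIM maps."""

import numpy as np
import pytest

from rotorflim.decay import IRF, DecayHistogram
from rotorflim.synthetic import (
    DecaySpec,
    SceneObject,
    SceneSpec,
    generate_decay,
    generate_flim_cube,
)
from rotorflim.tcspc import (
    DecayModel,
    component_map,
    convolve_model,
    fit_decay,
    fit_flim,
    lifetime_histogram,
    mean_lifetime,
)


@pytest.fixture(scope="module")
def grid():
    n, dt = 256, 50_000.0 / 256
    return n, dt


class TestConvolveModel:
    def test_delta_irf_gives_pure_exponential(self, grid):
        n, dt = grid
        irf = IRF.gaussian(n, dt, fwhm_ps=0.0, center_ps=0.0)
        m = convolve_model(irf, [1.0], [2500.0], period=1e12)  # wrap negligible
        t = (np.arange(n) + 0.5) * dt
        np.testing.assert_allclose(m, np.exp(-t / 2500.0), rtol=1e-9)

    def test_linear_in_amplitude(self, grid):
        n, dt = grid
        irf = IRF.gaussian(n, dt)
        m1 = convolve_model(irf, [1.0], [2500.0], offset=3.0)
        m2 = convolve_model(irf, [2.0], [2500.0], offset=3.0)
        np.testing.assert_allclose(m2 - 3.0, 2.0 * (m1 - 3.0),
                                   rtol=1e-12, atol=1e-9)

    def test_additive_in_components(self, grid):
        n, dt = grid
        irf = IRF.gaussian(n, dt)
        full = convolve_model(irf, [1.0], [2500.0])
        halves = convolve_model(irf, [0.5, 0.5], [2500.0, 2500.0000001])
        np.testing.assert_allclose(halves, full, rtol=1e-6)

    def test_grid_mismatch_rejected(self, grid):
        n, dt = grid
        irf = IRF.gaussian(n // 2, dt)
        with pytest.raises(ValueError, match="grid"):
            convolve_model(irf, [1.0], [2500.0], n_channels=n, dt=dt)


class TestFitDecay:
    def test_mono_exponential_recovery_within_2pc(self, mono_decay, default_irf):
        res = fit_decay(mono_decay, default_irf, n_components=1)
        assert res.converged
        assert res.lifetimes_ps[0] == pytest.approx(2473.0, rel=0.02)

    def test_low_count_regime_median_within_15pc(self):
        errs = []
        for seed in range(100):
            spec = DecaySpec(lifetimes_ps=(2473.0,), total_counts=300.0, seed=seed)
            res = fit_decay(generate_decay(spec), spec.build_irf())
            errs.append(abs(res.lifetimes_ps[0] - 2473.0) / 2473.0)
        assert np.median(errs) < 0.15

    def test_noiseless_self_consistency_from_perturbed_init(self):
        spec = DecaySpec(
            amplitudes=(2.0, 1.0), lifetimes_ps=(800.0, 3000.0),
            offset=0.5, total_counts=1e5, poisson_noise=False,
        )
        hist = generate_decay(spec)
        res = DecayModel(hist, spec.build_irf(), 2).fit(
            start={"lifetimes_ps": [500.0, 5000.0]}
        )
        np.testing.assert_allclose(res.lifetimes_ps, [800.0, 3000.0], rtol=1e-5)
        assert res.chisq_reduced < 1e-8

    def test_lifetimes_sorted_ascending(self):
        spec = DecaySpec(amplitudes=(1.0, 1.0), lifetimes_ps=(600.0, 4000.0),
                         total_counts=1e6, seed=3)
        res = fit_decay(generate_decay(spec), spec.build_irf(), n_components=2)
        assert np.all(np.diff(res.lifetimes_ps) > 0)

    def test_chi2_non_increasing_with_more_components(self, mono_decay, default_irf):
        chi1 = fit_decay(mono_decay, default_irf, 1).chisq_reduced
        chi2 = fit_decay(mono_decay, default_irf, 2).chisq_reduced
        assert chi2 <= chi1 * 1.01  # equal up to dof renormalisation

    def test_invariant_to_intensity_rescaling(self, mono_spec, default_irf):
        hist = generate_decay(mono_spec)
        scaled = DecayHistogram(hist.time_ps, hist.counts * 7.0)
        a = fit_decay(hist, default_irf, objective="weighted-ls")
        b = fit_decay(scaled, default_irf, objective="weighted-ls")
        # invariance is exact except for the unit floor on empty channels,
        # whose relative weight changes with the overall scale
        assert b.lifetimes_ps[0] == pytest.approx(a.lifetimes_ps[0], rel=0.01)
        assert b.amplitudes[0] == pytest.approx(7.0 * a.amplitudes[0], rel=5e-2)

    def test_degenerate_components_flagged(self):
        spec = DecaySpec(lifetimes_ps=(2500.0,), total_counts=1e5,
                         seed=5)
        hist = generate_decay(spec)
        with pytest.warns(UserWarning, match="merged"):
            res = fit_decay(hist, spec.build_irf(), n_components=2)
        assert res.degenerate

    def test_empty_histogram_flagged_not_raised(self, grid):
        n, dt = grid
        hist = DecayHistogram(np.arange(n) * dt, np.zeros(n))
        res = fit_decay(hist, IRF.gaussian(n, dt))
        assert not res.converged


class TestMeanLifetime:
    def _fit(self, amps, taus):
        from rotorflim.tcspc import DecayFitResults

        k = len(amps)
        return DecayFitResults(
            amplitudes=np.array(amps, float), lifetimes_ps=np.array(taus, float),
            offset=0.0, shift_ps=0.0, chisq_reduced=1.0, converged=True,
            objective="poisson", bse_amplitudes=np.zeros(k),
            bse_lifetimes=np.zeros(k), bse_offset=0.0, bse_shift=0.0,
        )

    def test_single_component_both_conventions_agree(self):
        fit = self._fit([2.0], [1500.0])
        assert mean_lifetime(fit, "amplitude") == 1500.0
        assert mean_lifetime(fit, "intensity") == 1500.0

    def test_amplitude_weighting_is_arithmetic_mean(self):
        fit = self._fit([1.0, 1.0], [1000.0, 3000.0])
        assert mean_lifetime(fit, "amplitude") == pytest.approx(2000.0)

    def test_intensity_weighting_favours_long_component(self):
        fit = self._fit([1.0, 1.0], [1000.0, 3000.0])
        assert mean_lifetime(fit, "intensity") == pytest.approx(2500.0)

    def test_all_zero_amplitudes_flagged_nan(self):
        fit = self._fit([0.0], [1000.0])
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(mean_lifetime(fit))


@pytest.fixture(scope="module")
def two_object_cube():
    scene = SceneSpec(
        objects=(
            SceneObject((4, 4), 2.5, (2200.0,), expected_counts=20000.0),
            SceneObject((11, 11), 2.5, (3400.0,), expected_counts=20000.0),
        ),
        shape=(16, 16),
    )
    dd = DecaySpec(seed=17)
    cube, truth = generate_flim_cube(scene, dd)
    return cube, truth, dd.build_irf()


@pytest.fixture(scope="module")
def fitted_map():
    scene = SceneSpec(
        objects=(SceneObject((4, 4), 2.5, (2500.0,), expected_counts=15000.0),),
        shape=(9, 9),
    )
    dd = DecaySpec(seed=29)
    cube, _ = generate_flim_cube(scene, dd)
    return fit_flim(cube, dd.build_irf(), count_threshold=1000)


class TestFitFlim:
    def test_two_object_scene_recovered_within_3pc(self, two_object_cube):
        cube, truth, irf = two_object_cube
        lm = fit_flim(cube, irf, count_threshold=1000)
        fitted = lm.mean_lifetime_map()
        true_map = truth.mean_lifetime_map()
        for tau in (2200.0, 3400.0):
            sel = (true_map == tau) & lm.mask
            assert np.nanmedian(fitted[sel]) == pytest.approx(tau, rel=0.03)

    def test_threshold_above_counts_raises_empty_mask(self, two_object_cube):
        cube, _, irf = two_object_cube
        with pytest.raises(ValueError, match="empty mask"):
            fit_flim(cube, irf, count_threshold=10**9)

    def test_binning_on_uniform_scene_matches_unbinned(self):
        scene = SceneSpec(
            objects=(SceneObject((5, 5), 12.0, (2500.0,), expected_counts=3000.0),),
            shape=(11, 11),
        )
        dd = DecaySpec(seed=23)
        cube, _ = generate_flim_cube(scene, dd)
        irf = dd.build_irf()
        plain = fit_flim(cube, irf, count_threshold=500)
        binned = fit_flim(cube, irf, spatial_binning=3, count_threshold=500)
        center = np.s_[2:9, 2:9]  # away from edge effects of the window
        m_plain = np.nanmedian(plain.mean_lifetime_map()[center])
        m_binned = np.nanmedian(binned.mean_lifetime_map()[center])
        assert m_binned == pytest.approx(m_plain, rel=0.02)
        # noise reduction: binned per-pixel spread should not be larger
        assert (np.nanstd(binned.mean_lifetime_map()[center])
                <= np.nanstd(plain.mean_lifetime_map()[center]) + 1e-9)

    def test_unfitted_pixels_are_nan_not_zero(self, two_object_cube):
        cube, _, irf = two_object_cube
        lm = fit_flim(cube, irf, count_threshold=1000)
        assert np.all(np.isnan(lm.lifetimes[~lm.mask]))


class TestComponentMapAndHistogram:
    def test_single_component_map_equals_lifetime_map(self, fitted_map):
        cm = component_map(fitted_map, 1)
        np.testing.assert_array_equal(
            cm[fitted_map.mask], fitted_map.mean_lifetime_map()[fitted_map.mask]
        )

    def test_index_beyond_components_rejected(self, fitted_map):
        with pytest.raises(ValueError, match="beyond"):
            component_map(fitted_map, 3)

    def test_mask_propagates_to_component_map(self, fitted_map):
        cm = component_map(fitted_map, 1)
        assert np.all(np.isnan(cm[~fitted_map.mask]))

    def test_histogram_counts_sum_to_mask_size(self, fitted_map):
        hist, _ = lifetime_histogram(fitted_map, bins=20)
        assert hist.sum() == fitted_map.mask.sum()

    def test_uniform_map_occupies_single_bin(self):
        arr = np.full((5, 5), 2500.0)
        hist, _ = lifetime_histogram(arr, range=(2000.0, 3000.0), bins=10)
        assert np.count_nonzero(hist) == 1

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            lifetime_histogram(np.full((4, 4), np.nan))


class TestThirdComponentRecovery:
    def test_three_component_mixture_third_lifetime_mode(self):
        # mixture resolvable on the 1024-channel grid; tau_3 truth 3500 ps
        spec = DecaySpec(
            amplitudes=(1.0, 1.0, 1.0), lifetimes_ps=(500.0, 1500.0, 3500.0),
            total_counts=2e6, n_channels=1024, seed=31,
        )
        hist = generate_decay(spec)
        res = fit_decay(hist, spec.build_irf(), n_components=3)
        assert res.lifetimes_ps[2] == pytest.approx(3500.0, rel=0.10)
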