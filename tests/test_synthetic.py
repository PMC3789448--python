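"""Synthetic acquisition chain, phantoms and noise models."""

import numpy as np
import pytest

from skinmaps import (
    AcquisitionModel,
    SkinParams,
    add_noise,
    make_filterbank,
    make_ischemia_series,
    make_skin_phantom,
    make_training_chart,
    make_training_set,
    simulate_acquisition,
)


class TestFilterBank:
    def test_default_has_ten_filters_spanning_vis_nir(self):
        bank = make_filterbank()
        assert bank.n_filters == 10
        assert bank.centres[0] == 420.0 and bank.centres[-1] == 960.0

    def test_half_transmittance_at_half_width(self):
        bank = make_filterbank()
        lam = bank.centres + bank.fwhm / 2
        trans = bank.transmittance(lam)
        np.testing.assert_allclose(np.diagonal(trans), 0.5, rtol=1e-12)

    def test_neighbouring_filters_overlap(self):
        bank = make_filterbank()
        midpoints = 0.5 * (bank.centres[:-1] + bank.centres[1:])
        trans = bank.transmittance(midpoints)
        for i, lam in enumerate(midpoints):
            assert trans[i, i] > 0.1 and trans[i + 1, i] > 0.1

    def test_rejects_empty_or_unsorted(self):
        with pytest.raises(ValueError):
            make_filterbank(centres=np.array([]))
        with pytest.raises(ValueError):
            make_filterbank(centres=np.array([500.0, 450.0]))


def _quiet_model(**kw):
    return AcquisitionModel(read_noise_dn=0.0, electrons_per_dn=0.0, **kw)


class TestSimulateAcquisition:
    def test_black_scene_returns_offset_field(self, grid):
        model = _quiet_model()
        cube = np.zeros((6, 6, len(grid)))
        acq = simulate_acquisition(cube, grid, model=model, seed=0)
        expected = np.round(model.offset_field((6, 6)))
        for b in range(acq.raw.shape[-1]):
            np.testing.assert_array_equal(acq.raw[..., b], expected)

    def test_narrowband_limit_reads_reflectance_at_centres(self, grid):
        # flat chain + delta-narrow filters: corrected signal tracks r(centre)
        lam_model = np.arange(400.0, 1000.0 + 1, 2.0)
        model = _quiet_model(
            illuminant=np.ones_like(lam_model),
            optics=np.ones_like(lam_model),
            sensor=np.ones_like(lam_model),
            vignetting_strength=0.0,
            gain_gradient=0.0,
        )
        bank = make_filterbank(fwhm=4.0)
        r = 0.2 + 0.5 * (grid.wavelengths - 420.0) / 360.0  # linear ramp in the visible
        cube = np.tile(r, (3, 3, 1))
        acq = simulate_acquisition(cube, grid, model=model, bank=bank, seed=0)
        corrected = acq.corrected()[1, 1]
        predicted = []
        for c in bank.centres:
            r_c = float(np.interp(c, grid.wavelengths, r))
            predicted.append(4096.0 * (r_c - 0.02) / 0.97)
        np.testing.assert_allclose(corrected, predicted, rtol=0.02)

    def test_saturation_fraction_reported(self, grid):
        model = _quiet_model(full_scale_fraction=1.5)
        cube = np.full((4, 4, len(grid)), 0.99)
        acq = simulate_acquisition(cube, grid, model=model, seed=0)
        assert acq.saturation_fraction > 0.0

    def test_round_trip_recovers_linear_reflectance_scale(self, grid):
        # calibration removes gain/offset: two grey scenes stay proportional
        model = _quiet_model()
        resp = []
        for level in (0.3, 0.6):
            cube = np.full((5, 5, len(grid)), level)
            acq = simulate_acquisition(cube, grid, model=model, seed=1)
            resp.append(np.nanmean(acq.corrected(), axis=(0, 1)))
        ratio = resp[1] / resp[0]
        np.testing.assert_allclose(ratio, (0.6 - 0.02) / (0.3 - 0.02), rtol=0.01)


class TestTrainingChart:
    def test_chart_is_24_smooth_in_gamut_patches(self, grid):
        chart = make_training_chart(grid)
        assert chart.shape == (24, len(grid))
        assert chart.min() >= 0.02 and chart.max() <= 0.98
        assert np.max(np.abs(np.diff(chart, axis=1))) < 0.2

    def test_training_set_shapes_and_determinism(self, grid):
        a = make_training_set(seed=3)
        b = make_training_set(seed=3)
        assert a.responses.shape == (24, 10)
        assert a.spectra.shape == (24, len(grid))
        np.testing.assert_array_equal(a.responses, b.responses)


class TestSkinPhantom:
    def test_reproducible_from_seed(self):
        base = SkinParams(0.12, 0.05, 0.02, 0.7, 1.0)
        a = make_skin_phantom(base, shape=(8, 8), seed=9)
        b = make_skin_phantom(base, shape=(8, 8), seed=9)
        np.testing.assert_array_equal(a.cube.data, b.cube.data)

    def test_no_lesion_has_no_mask_and_smooth_maps(self):
        phantom = make_skin_phantom(SkinParams(0.12, 0.05, 0.02, 0.7, 1.0), shape=(16, 16), seed=1)
        assert phantom.lesion_mask is None
        f = phantom.maps["f_mel"]
        assert np.max(np.abs(np.diff(f, axis=0))) < 0.05 * f.mean()

    def test_vitiligo_melanin_ratio_matches_factor(self):
        phantom = make_skin_phantom(
            SkinParams(0.15, 0.05, 0.02, 0.7, 1.0), lesion="vitiligo", factor=0.27, shape=(24, 24), seed=2
        )
        ratio = (
            phantom.maps["f_mel"][phantom.lesion_mask].mean()
            / phantom.maps["f_mel"][~phantom.lesion_mask].mean()
        )
        assert ratio == pytest.approx(0.27, rel=0.02)

    def test_melasma_melanin_ratio_matches_factor(self):
        phantom = make_skin_phantom(
            SkinParams(0.15, 0.05, 0.02, 0.7, 1.0), lesion="melasma", factor=2.06, shape=(24, 24), seed=2
        )
        ratio = (
            phantom.maps["f_mel"][phantom.lesion_mask].mean()
            / phantom.maps["f_mel"][~phantom.lesion_mask].mean()
        )
        assert ratio == pytest.approx(2.06, rel=0.02)

    def test_out_of_bounds_lesion_clipped_with_warning(self, bounds):
        with pytest.warns(UserWarning):
            phantom = make_skin_phantom(
                SkinParams(0.30, 0.05, 0.02, 0.7, 1.0), lesion="melasma", factor=2.0, shape=(8, 8), seed=0
            )
        assert phantom.maps["f_mel"].max() <= bounds.intervals["f_mel"][1]

    def test_lesion_direction_enforced(self):
        base = SkinParams(0.15, 0.05, 0.02, 0.7, 1.0)
        with pytest.raises(ValueError):
            make_skin_phantom(base, lesion="vitiligo", factor=1.5)
        with pytest.raises(ValueError):
            make_skin_phantom(base, lesion="melasma", factor=0.5)


class TestIschemiaSeries:
    BASELINE = SkinParams(0.133, 0.0149, 0.016, 0.719, 1.02)

    def test_unit_scales_give_identical_phantoms(self):
        a1, a2, a3 = make_ischemia_series(
            self.BASELINE, 1.0, 1.0, 1.0, 1.0, shape=(8, 8), seed=4
        )
        np.testing.assert_array_equal(a1.cube.data, a2.cube.data)
        np.testing.assert_array_equal(a1.cube.data, a3.cube.data)

    def test_default_occlusion_percentage_changes(self):
        # occlusion raises blood volume by 75 % and lowers oxygenation by 23 %
        a1, a2, _ = make_ischemia_series(self.BASELINE, shape=(8, 8), seed=4)
        for name, expected in (("f_blood", 75.0), ("c_oxy", -23.0)):
            m1, m2 = a1.maps[name].mean(), a2.maps[name].mean()
            assert 100.0 * (m2 - m1) / m1 == pytest.approx(expected, abs=0.01)

    def test_reperfusion_is_near_baseline(self):
        a1, _, a3 = make_ischemia_series(self.BASELINE, shape=(8, 8), seed=4)
        for name, expected in (("f_blood", 6.25), ("c_oxy", 6.6)):
            m1, m3 = a1.maps[name].mean(), a3.maps[name].mean()
            assert 100.0 * (m3 - m1) / m1 == pytest.approx(expected, abs=0.01)

    def test_melanin_and_thicknesses_unchanged(self):
        a1, a2, a3 = make_ischemia_series(self.BASELINE, shape=(8, 8), seed=4)
        for name in ("f_mel", "d_epi", "d_dermis"):
            np.testing.assert_array_equal(a1.maps[name], a2.maps[name])
            np.testing.assert_array_equal(a1.maps[name], a3.maps[name])


class TestAddNoise:
    def test_zero_amplitude_is_identity(self):
        x = np.linspace(0.1, 0.9, 20)
        np.testing.assert_array_equal(add_noise(x, 0.0, seed=0), x)

    def test_zero_mean_and_amplitude_containment(self):
        x = np.full(100_000, 0.5)
        noisy = add_noise(x, 0.1, seed=6)
        delta = noisy - x
        assert abs(delta.mean()) < 4 * (0.1 / 3) / np.sqrt(x.size)
        assert np.mean(np.abs(delta) <= 0.1) >= 0.99

    def test_clipped_to_valid_range(self):
        noisy = add_noise(np.zeros(10_000), 0.3, seed=1)
        assert noisy.min() >= 0.0

    def test_reproducible_per_seed(self):
        x = np.full(50, 0.4)
        np.testing.assert_array_equal(add_noise(x, 0.1, seed=3), add_noise(x, 0.1, seed=3))
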